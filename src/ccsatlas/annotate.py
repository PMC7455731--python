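"""Multi-dimensional metabolite annotation: m/z + CCS + MS/MS.

A measured feature (m/z, retention time, CCS, optional MS/MS spectrum) is
matched against a candidate database in up to three dimensions:

* **m/z match** -- candidates whose adduct m/z lies within a ppm
  tolerance (default 25 ppm; [M+H]+ / [M-H]- by default);
* **CCS match** -- a trapezoidal score of the relative CCS error
  Delta_rela = |CCS_cand - CCS_exp| / CCS_exp * 100: full score below
  TOL_min (2%), linear decay to zero at TOL_max (4%), candidates beyond
  TOL_max removed;
* **MS/MS match** -- reverse dot-product (weighted cosine over the
  reference library's peaks only; experimental-only peaks are ignored),
  with square-root intensity weighting.

Scores are fused as S = W_ccs * S_ccs + W_msms * S_msms with weights
0.3 / 0.7 and candidates are densely ranked by the integrated score.
Third-party in-silico MS/MS scores can be ingested instead of spectra;
they are min-max rescaled to [0, 1] within each feature's candidate set
before integration.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ccsatlas.adducts import AdductTable, default_adducts
from ccsatlas.chemio import Spectrum

__all__ = [
    "AnnotationResult",
    "Feature",
    "MatchTolerances",
    "ccs_score",
    "delta_rela",
    "integrated_score",
    "match_mz",
    "msms_score",
    "parse_feature_id",
    "rank_candidates",
    "rescale_scores",
]

DEFAULT_ANNOTATION_ADDUCTS = {"+": ["[M+H]+"], "-": ["[M-H]-"]}

_FEATURE_ID_RE = re.compile(r"^M(\d+)T(\d+)C(\d+)$")


@dataclass
class Feature:
    """A measured LC-IM-MS feature (id convention ``M<mz>T<rt>C<ccs>``)."""

    mz: float
    rt: float
    ccs: float
    polarity: str = "+"
    intensity: float = 0.0
    spectrum: Spectrum | None = None
    feature_id: str | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0 or self.ccs <= 0:
            raise ValueError("feature m/z and CCS must be positive")
        if self.feature_id is None:
            self.feature_id = f"M{round(self.mz)}T{round(self.rt)}C{round(self.ccs)}"


def parse_feature_id(feature_id: str) -> tuple[int, int, int]:
    """Split ``M384T767C189`` into rounded (m/z, RT, CCS)."""
    m = _FEATURE_ID_RE.match(feature_id)
    if not m:
        raise ValueError(f"malformed feature id {feature_id!r}")
    return tuple(int(g) for g in m.groups())


@dataclass
class MatchTolerances:
    """Tolerances and weights of the multi-dimensional match."""

    ppm: float = 25.0
    tol_min_pct: float = 2.0
    tol_max_pct: float = 4.0
    w_ccs: float = 0.3
    w_msms: float = 0.7
    msms_mz_ppm: float = 25.0

    def __post_init__(self) -> None:
        if not 0 <= self.tol_min_pct <= self.tol_max_pct:
            raise ValueError("need 0 <= TOL_min <= TOL_max")


# ---------------------------------------------------------------------------
# elementary scores
# ---------------------------------------------------------------------------


def delta_rela(ccs_candidate: float, ccs_experimental: float) -> float:
    """Relative CCS error in percent: |cand - exp| / exp * 100."""
    if ccs_candidate <= 0 or ccs_experimental <= 0:
        raise ValueError("CCS values must be positive")
    return abs(ccs_candidate - ccs_experimental) / ccs_experimental * 100.0


def ccs_score(delta_pct: float, tolerances: MatchTolerances | None = None) -> float:
    """Trapezoidal CCS match score.

    1 below TOL_min, linear decay on [TOL_min, TOL_max], 0 beyond.  With
    TOL_max == TOL_min the score degenerates to a step function at the
    shared tolerance.
    """
    tol = tolerances or MatchTolerances()
    if delta_pct < tol.tol_min_pct:
        return 1.0
    if delta_pct > tol.tol_max_pct:
        return 0.0
    if tol.tol_max_pct == tol.tol_min_pct:
        return 1.0
    return 1.0 - (delta_pct - tol.tol_min_pct) / (tol.tol_max_pct - tol.tol_min_pct)


def integrated_score(
    s_ccs: float,
    s_msms: float,
    tolerances: MatchTolerances | None = None,
    allow_unnormalized: bool = False,
) -> float:
    """Weighted fusion W_ccs * S_ccs + W_msms * S_msms (weights 0.3/0.7)."""
    tol = tolerances or MatchTolerances()
    if not allow_unnormalized and abs(tol.w_ccs + tol.w_msms - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1 (or pass allow_unnormalized=True)")
    return tol.w_ccs * s_ccs + tol.w_msms * s_msms


def msms_score(
    experimental: Spectrum, reference: Spectrum, mz_tol_ppm: float = 25.0
) -> float:
    """Reverse dot-product spectral similarity in [0, 1].

    Computed over the reference peaks only: each reference peak is paired
    with the closest experimental peak within ``mz_tol_ppm`` (0 intensity
    when absent); experimental peaks without a reference counterpart are
    ignored.  Intensities are square-root transformed and the squared
    cosine of the two weight vectors is returned.  No aligned peaks give
    0, not an error.
    """
    ref = reference.canonicalize().peaks
    exp = experimental.canonicalize().peaks
    matched = np.zeros(len(ref))
    for i, (mz, _) in enumerate(ref):
        tol = mz * mz_tol_ppm * 1e-6
        close = np.abs(exp[:, 0] - mz) <= tol
        if close.any():
            matched[i] = exp[close, 1].max()
    w_ref = np.sqrt(ref[:, 1])
    w_exp = np.sqrt(matched)
    denom = np.linalg.norm(w_ref) * np.linalg.norm(w_exp)
    if denom == 0:
        return 0.0
    cos = float(np.dot(w_ref, w_exp) / denom)
    return cos * cos


def rescale_scores(values) -> np.ndarray:
    """Min-max rescale raw (e.g. third-party in-silico) scores to [0, 1]
    within a candidate set; a constant set maps to all ones."""
    values = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(values), np.nanmax(values)
    if hi == lo:
        return np.ones_like(values)
    return (values - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# candidate retrieval & ranking
# ---------------------------------------------------------------------------


def match_mz(
    feature: Feature,
    database: pd.DataFrame,
    tolerances: MatchTolerances | None = None,
    adducts: list[str] | None = None,
    adduct_table: AdductTable | None = None,
) -> pd.DataFrame:
    """Candidates whose adduct m/z is within the ppm tolerance.

    ``database`` needs columns ``id`` and ``mass`` (neutral monoisotopic);
    other columns pass through.  One output row per candidate x adduct,
    with ``adduct``, ``theoretical_mz`` and signed ``ppm_error`` added.
    """
    if database.empty:
        raise ValueError("candidate database is empty")
    tol = tolerances or MatchTolerances()
    table = adduct_table or default_adducts()
    adducts = adducts or DEFAULT_ANNOTATION_ADDUCTS[feature.polarity]
    out = []
    for adduct in adducts:
        spec = table.get(adduct)
        theo = database["mass"].astype(float) + spec.mass_shift
        ppm = (feature.mz - theo) / theo * 1e6
        hits = database[np.abs(ppm) <= tol.ppm].copy()
        hits["adduct"] = spec.name
        hits["theoretical_mz"] = theo[np.abs(ppm) <= tol.ppm]
        hits["ppm_error"] = ppm[np.abs(ppm) <= tol.ppm]
        out.append(hits)
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame()


@dataclass
class AnnotationResult:
    """Ranked candidates for one feature plus per-stage candidate counts."""

    feature_id: str
    candidates: pd.DataFrame
    n_mz_matched: int
    n_after_ccs: int
    n_ranked: int
    used_ccs_fallback: bool = False

    @property
    def reduction_fraction(self) -> float:
        """Fraction of m/z candidates removed by the CCS dimension."""
        if self.n_mz_matched == 0:
            return 0.0
        return 1.0 - self.n_after_ccs / self.n_mz_matched


def rank_candidates(
    feature: Feature,
    database: pd.DataFrame,
    tolerances: MatchTolerances | None = None,
    use_ccs: bool = True,
    use_msms: bool = True,
    reference_spectra: dict[str, Spectrum] | None = None,
    external_msms_scores: dict[str, float] | None = None,
    adducts: list[str] | None = None,
    adduct_table: AdductTable | None = None,
) -> AnnotationResult:
    """Full multi-dimensional match for one feature.

    Pipeline: m/z filter -> optional CCS filter + trapezoid score ->
    optional MS/MS score (reverse dot-product against
    ``reference_spectra``, or pre-computed ``external_msms_scores``
    min-max rescaled per feature) -> integrated score -> dense descending
    ranking with ties broken by |ppm error| then id.

    ``database`` columns: ``id``, ``mass`` and (for CCS scoring) ``ccs``
    plus optionally ``ccs_source``.  Candidates without a CCS value are
    excluded when CCS filtering is on.  A feature without usable MS/MS
    falls back to S_ccs with the CCS weight renormalized to 1 (flagged on
    the result).
    """
    if not (use_ccs or use_msms):
        raise ValueError("at least one scoring dimension must be enabled")
    tol = tolerances or MatchTolerances()
    cand = match_mz(feature, database, tol, adducts, adduct_table)
    n_mz = len(cand)

    if use_ccs and n_mz:
        has_ccs = cand["ccs"].notna()
        delta = np.array(
            [delta_rela(c, feature.ccs) if ok else np.inf for c, ok in zip(cand["ccs"], has_ccs)]
        )
        keep = delta <= tol.tol_max_pct
        cand = cand[keep].copy()
        cand["delta_rela_pct"] = delta[keep]
        cand["s_ccs"] = [ccs_score(d, tol) for d in cand["delta_rela_pct"]]
    elif n_mz:
        cand = cand.copy()
        cand["delta_rela_pct"] = np.nan
        cand["s_ccs"] = np.nan
    n_ccs = len(cand)

    fallback = False
    if len(cand):
        if use_msms and external_msms_scores is not None:
            raw = np.array([external_msms_scores.get(i, np.nan) for i in cand["id"]], float)
            raw = np.where(np.isnan(raw), np.nanmin(raw) if np.isfinite(np.nanmin(raw)) else 0.0, raw)
            cand["s_msms"] = rescale_scores(raw)
        elif use_msms and feature.spectrum is not None and reference_spectra:
            cand["s_msms"] = [
                msms_score(feature.spectrum, reference_spectra[i], tol.msms_mz_ppm)
                if i in reference_spectra
                else 0.0
                for i in cand["id"]
            ]
        else:
            fallback = use_msms  # MS/MS requested but unavailable
            cand["s_msms"] = np.nan

        if use_ccs and use_msms and not fallback:
            cand["s_integrated"] = [
                integrated_score(c, m, tol) for c, m in zip(cand["s_ccs"], cand["s_msms"])
            ]
        elif use_msms and not fallback and not use_ccs:
            cand["s_integrated"] = cand["s_msms"]
        else:  # CCS only (either by request or by fallback)
            cand["s_integrated"] = cand["s_ccs"]

        cand["abs_ppm_error"] = cand["ppm_error"].abs()
        cand = cand.sort_values(
            ["s_integrated", "abs_ppm_error", "id"],
            ascending=[False, True, True],
            kind="stable",
        ).reset_index(drop=True)
        cand["rank"] = (
            cand["s_integrated"].rank(method="dense", ascending=False).astype(int)
        )
        cand = cand.drop(columns="abs_ppm_error")

    return AnnotationResult(
        feature_id=feature.feature_id,
        candidates=cand,
        n_mz_matched=n_mz,
        n_after_ccs=n_ccs,
        n_ranked=len(cand),
        used_ccs_fallback=fallback,
    )
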