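"""Representative structure similarity (RSS).

RSS estimates how reliable a predicted CCS is by asking how structurally
close the query compound sits to the model's training set: tanimoto
coefficients (TC) between molecular fingerprints are computed against all
training structures and the mean of the top five is the RSS score.
Queries are binned into small (RSS <= 0.6), medium (0.6 < RSS <= 0.8) and
large (RSS > 0.8) reliability groups; large-RSS predictions carry the
smallest errors.

The default fingerprint is path-based (depth 7, 1024 bits).  Published
RSS values can shift by a few hundredths across fingerprint schemes, so
the scheme is recorded in every result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit.Chem import rdFingerprintGenerator

from ccsatlas.chemio import mol_from_structure

__all__ = [
    "Fingerprint",
    "FingerprintScheme",
    "RSSResult",
    "fingerprint",
    "rss_group",
    "rss_score",
    "tanimoto",
]


@dataclass(frozen=True)
class FingerprintScheme:
    algorithm: str = "rdkit-path"
    depth: int = 7
    n_bits: int = 1024

    @property
    def id(self) -> str:
        return f"{self.algorithm}/d{self.depth}/{self.n_bits}"


DEFAULT_SCHEME = FingerprintScheme()


@dataclass
class Fingerprint:
    """Fixed-length bitset plus the scheme that produced it."""

    bits: np.ndarray  # bool vector
    scheme: str = DEFAULT_SCHEME.id
    source_id: str | None = None

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())


def fingerprint(
    structure: str,
    scheme: FingerprintScheme = DEFAULT_SCHEME,
    source_id: str | None = None,
) -> Fingerprint:
    """Path-based fingerprint of a SMILES/InChI structure."""
    mol = mol_from_structure(structure)
    if mol is None:
        raise ValueError(f"structure does not parse: {structure!r}")
    gen = rdFingerprintGenerator.GetRDKitFPGenerator(
        maxPath=scheme.depth, fpSize=scheme.n_bits
    )
    arr = np.array(gen.GetFingerprint(mol), dtype=bool)
    return Fingerprint(arr, scheme.id, source_id)


def tanimoto(fp_a: Fingerprint, fp_b: Fingerprint) -> float:
    """Tanimoto coefficient |A & B| / (|A| + |B| - |A & B|).

    Defined as 1.0 when both bitsets are empty (identical nothingness).
    """
    if fp_a.scheme != fp_b.scheme:
        raise ValueError(f"fingerprint scheme mismatch: {fp_a.scheme} vs {fp_b.scheme}")
    inter = int((fp_a.bits & fp_b.bits).sum())
    union = fp_a.popcount + fp_b.popcount - inter
    if union == 0:
        return 1.0
    return inter / union


def rss_group(rss: float) -> str:
    """Reliability group of an RSS score: small <= 0.6 < medium <= 0.8 < large."""
    if not 0.0 <= rss <= 1.0:
        raise ValueError(f"RSS must lie in [0, 1], got {rss}")
    if rss <= 0.6:
        return "small"
    if rss <= 0.8:
        return "medium"
    return "large"


@dataclass
class RSSResult:
    rss: float
    top_tcs: list[float]
    nearest_training_ids: list[str | None]
    group: str
    scheme: str = DEFAULT_SCHEME.id


def rss_score(
    query: Fingerprint | str,
    training_fingerprints: list[Fingerprint],
    top_k: int = 5,
    exclude_self: bool = False,
) -> RSSResult:
    """RSS of a query against the training set: mean of the top ``top_k``
    tanimoto coefficients (fewer when the training set is smaller).

    ``exclude_self`` drops perfect self-matches (TC exactly 1 against an
    identical training structure) for leave-one-out experiments; by
    default a query identical to a training structure scores 1.
    """
    if not training_fingerprints:
        raise ValueError("training set must hold at least one fingerprint")
    if isinstance(query, str):
        scheme_id = training_fingerprints[0].scheme
        base = DEFAULT_SCHEME
        if scheme_id != base.id:
            algo, depth, bits = scheme_id.split("/")
            base = FingerprintScheme(algo, int(depth[1:]), int(bits))
        query = fingerprint(query, base)
    tcs = np.array([tanimoto(query, fp) for fp in training_fingerprints])
    ids = np.array([fp.source_id for fp in training_fingerprints], dtype=object)
    if exclude_self:
        keep = ~np.isclose(tcs, 1.0)
        if keep.any():
            tcs, ids = tcs[keep], ids[keep]
    order = np.argsort(-tcs, kind="stable")[: min(top_k, len(tcs))]
    top = tcs[order]
    rss = float(top.mean())
    return RSSResult(
        rss=rss,
        top_tcs=[float(t) for t in top],
        nearest_training_ids=list(ids[order]),
        group=rss_group(rss),
        scheme=query.scheme,
    )
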