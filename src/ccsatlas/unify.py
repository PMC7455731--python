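"""Standardization of multi-source experimental CCS records.

Raw collision cross-section measurements collected from independent
datasets, labs and instrument families (drift tube DTIM, traveling wave
TWIM, trapped TIMS) disagree by instrument calibration and lab bias.  This
module turns them into one consensus ("unified") CCS per compound x adduct
through a five-step procedure:

1. quality check (structure present, whitelisted adduct, m/z error <= 10 ppm);
2. intra-dataset consistency (replicates within 0.5% are averaged, worse
   groups removed);
3. trend-line outlier removal (per chemical superclass, CCS vs ion m/z is
   fitted by a power function on log-log axes and records outside the
   two-sided 99% prediction interval are dropped);
4. DTIM-priority averaging into the unified value;
5. confidence-level assignment (1 / 2 / 3 / Conflict; level 4 is reserved
   for predicted values).

Every input record ends up either in exactly one unified value's source
list or in exactly one removal report row, so the pipeline is auditable.

Record tables are DataFrames with columns ``record_id, compound_id,
adduct, ccs, mz_reported, dataset_id, lab_id, instrument, polarity``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ccsatlas.adducts import AdductTable, compute_adduct_mz, default_adducts, ppm_error

__all__ = [
    "INSTRUMENTS",
    "UnifyConfig",
    "assign_confidence",
    "compute_unified_ccs",
    "max_diff_pct",
    "merge_within_dataset",
    "quality_filter",
    "remove_trendline_outliers",
    "unify_pipeline",
]

INSTRUMENTS = ("DTIM", "TWIM", "TIMS")

RECORD_COLUMNS = [
    "record_id", "compound_id", "adduct", "ccs", "mz_reported",
    "dataset_id", "lab_id", "instrument", "polarity",
]


@dataclass
class UnifyConfig:
    """Thresholds of the standardization pipeline (defaults as published)."""

    ppm_max: float = 10.0
    intra_dataset_max_diff_pct: float = 0.5
    min_class_n: int = 10
    pi_level: float = 0.99
    level1_max_diff_pct: float = 1.0
    level2_max_diff_pct: float = 3.0


def max_diff_pct(values) -> float:
    """Maximum pairwise CCS difference as % of the group mean: (max-min)/mean*100."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        return 0.0
    return (values.max() - values.min()) / values.mean() * 100.0


def _removal(records: pd.DataFrame, stage: str, reason: str) -> pd.DataFrame:
    out = records[["record_id"]].copy()
    out["stage"] = stage
    out["reason"] = reason
    return out


def quality_filter(
    records: pd.DataFrame,
    compounds: pd.DataFrame,
    adduct_table: AdductTable | None = None,
    ppm_max: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove records without structures, with non-whitelist adducts, or
    with reported m/z deviating > ``ppm_max`` ppm from the theoretical
    adduct m/z.  Records lacking a reported m/z pass the ppm sub-check.
    """
    table = adduct_table or default_adducts()
    comp = compounds.set_index("id")
    removals = []
    keep_mask = np.ones(len(records), dtype=bool)
    for i, (_, rec) in enumerate(records.iterrows()):
        cid = rec["compound_id"]
        structure_ok = (
            cid in comp.index
            and comp.loc[cid].get("parsed", True)
            and isinstance(comp.loc[cid, "smiles"], str)
        )
        if not structure_ok:
            removals.append((rec["record_id"], "no chemical structure"))
            keep_mask[i] = False
            continue
        if rec["adduct"] not in table:
            removals.append((rec["record_id"], f"adduct {rec['adduct']} not whitelisted"))
            keep_mask[i] = False
            continue
        if pd.notna(rec.get("mz_reported")):
            theo = compute_adduct_mz(comp.loc[cid, "mass"], rec["adduct"], table)
            if ppm_error(rec["mz_reported"], theo) > ppm_max:
                removals.append((rec["record_id"], f"m/z error > {ppm_max:g} ppm"))
                keep_mask[i] = False
    rem = pd.DataFrame(removals, columns=["record_id", "reason"])
    rem.insert(1, "stage", "quality")
    return records[keep_mask].reset_index(drop=True), rem


def merge_within_dataset(
    records: pd.DataFrame, max_diff: float = 0.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse replicate records within a dataset.

    Per (dataset, compound, adduct) group: if the maximum CCS difference
    exceeds ``max_diff`` % the whole group is removed as inconsistent,
    otherwise the group is replaced by one record carrying the arithmetic
    mean CCS.  The merged record tracks its sources in
    ``source_record_ids``.
    """
    merged_rows, removals = [], []
    for _, grp in records.groupby(["dataset_id", "compound_id", "adduct"], sort=False):
        diff = max_diff_pct(grp["ccs"])
        if diff > max_diff:
            removals.append(_removal(grp, "intra-dataset", f"replicate spread {diff:.2f}% > {max_diff:g}%"))
            continue
        row = grp.iloc[0].to_dict()
        row["ccs"] = float(grp["ccs"].mean())
        row["source_record_ids"] = list(grp["record_id"])
        merged_rows.append(row)
    merged = pd.DataFrame(merged_rows)
    rem = (
        pd.concat(removals, ignore_index=True)
        if removals
        else pd.DataFrame(columns=["record_id", "stage", "reason"])
    )
    return merged, rem


def _power_law_outliers(mz, ccs, pi_level: float) -> np.ndarray:
    """Boolean mask of points outside the two-sided OLS prediction interval
    of log(ccs) ~ log(mz)."""
    x, y = np.log(np.asarray(mz, float)), np.log(np.asarray(ccs, float))
    n = len(x)
    xbar = x.mean()
    sxx = ((x - xbar) ** 2).sum()
    if sxx <= 0:
        raise np.linalg.LinAlgError("degenerate fit: all m/z identical")
    beta = ((x - xbar) * (y - y.mean())).sum() / sxx
    alpha = y.mean() - beta * xbar
    resid = y - (alpha + beta * x)
    s2 = (resid**2).sum() / (n - 2)
    if s2 < 1e-20:  # numerically perfect power law: nothing to remove
        return np.zeros(n, dtype=bool)
    tval = stats.t.ppf(0.5 + pi_level / 2.0, n - 2)
    half = tval * np.sqrt(s2 * (1.0 + 1.0 / n + (x - xbar) ** 2 / sxx))
    return np.abs(resid) > half


def remove_trendline_outliers(
    records: pd.DataFrame,
    compounds: pd.DataFrame,
    adduct_table: AdductTable | None = None,
    min_class_n: int = 10,
    pi_level: float = 0.99,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop CCS records falling outside the per-superclass power-law trend.

    Per (superclass, polarity) with >= ``min_class_n`` records, CCS = a * (m/z)^b
    is fitted by least squares on log-log axes; records outside the
    two-sided ``pi_level`` prediction interval are removed.  Smaller
    classes (and records without a superclass) are passed through.
    """
    table = adduct_table or default_adducts()
    comp = compounds.set_index("id")
    records = records.reset_index(drop=True)
    mz = np.array(
        [
            compute_adduct_mz(comp.loc[r["compound_id"], "mass"], r["adduct"], table)
            for _, r in records.iterrows()
        ]
    )
    superclass = records["compound_id"].map(comp["superclass"])
    drop_mask = np.zeros(len(records), dtype=bool)
    for (_, _), idx in records.groupby([superclass, records["polarity"]], sort=False).groups.items():
        idx = np.asarray(list(idx))
        if len(idx) < max(min_class_n, 3):
            continue
        try:
            out = _power_law_outliers(mz[idx], records.loc[idx, "ccs"].to_numpy(), pi_level)
        except np.linalg.LinAlgError as err:
            warnings.warn(f"trend line skipped: {err}")
            continue
        drop_mask[idx[out]] = True
    dropped = records[drop_mask]
    rem = _removal(dropped, "trendline", f"outside {pi_level:.0%} prediction interval")
    if "source_record_ids" in dropped.columns and len(dropped):
        # expand merged records back to their raw sources for the audit trail
        rows = []
        for _, r in dropped.iterrows():
            for rid in r.get("source_record_ids") or [r["record_id"]]:
                rows.append((rid, "trendline", f"outside {pi_level:.0%} prediction interval"))
        rem = pd.DataFrame(rows, columns=["record_id", "stage", "reason"])
    return records[~drop_mask].reset_index(drop=True), rem


def assign_confidence(
    n_datasets: int,
    n_dtim_datasets: int,
    diff_pct: float,
    config: UnifyConfig | None = None,
) -> str:
    """Confidence level of a unified CCS value.

    Ordered cascade: Level ``1`` needs >= 2 independent DTIM datasets and a
    maximum difference <= 1%; else Level ``2`` needs >= 2 datasets across
    commercial instruments within 3%; >= 2 datasets beyond 3% is
    ``Conflict``; a single dataset is Level ``3``.
    """
    cfg = config or UnifyConfig()
    if n_datasets >= 2 and n_dtim_datasets >= 2 and diff_pct <= cfg.level1_max_diff_pct:
        return "1"
    if n_datasets >= 2 and diff_pct <= cfg.level2_max_diff_pct:
        return "2"
    if n_datasets >= 2:
        return "Conflict"
    return "3"


def compute_unified_ccs(
    records: pd.DataFrame, config: UnifyConfig | None = None
) -> pd.DataFrame:
    """DTIM-priority consensus per (compound, adduct) with confidence levels.

    If a group holds any drift-tube (DTIM) measurements the unified value
    averages those only; otherwise it averages all platforms.  The maximum
    difference is computed across all platform records of the group.
    """
    cfg = config or UnifyConfig()
    rows = []
    for (cid, adduct), grp in records.groupby(["compound_id", "adduct"], sort=True):
        dtim = grp[grp["instrument"] == "DTIM"]
        pool = dtim if len(dtim) else grp
        unified = float(pool["ccs"].mean())
        diff = max_diff_pct(grp["ccs"])
        n_datasets = grp["dataset_id"].nunique()
        n_dtim = dtim["dataset_id"].nunique()
        sources: list[str] = []
        for _, r in grp.iterrows():
            srcs = r.get("source_record_ids")
            sources.extend(srcs if isinstance(srcs, list) else [r["record_id"]])
        rows.append(
            {
                "compound_id": cid,
                "adduct": adduct,
                "unified_ccs": unified,
                "level": assign_confidence(n_datasets, n_dtim, diff, cfg),
                "n_datasets": n_datasets,
                "n_dtim_datasets": n_dtim,
                "max_diff_pct": diff,
                "polarity": grp["polarity"].iloc[0],
                "source_record_ids": sources,
            }
        )
    return pd.DataFrame(rows)


def unify_pipeline(
    records: pd.DataFrame,
    compounds: pd.DataFrame,
    adduct_table: AdductTable | None = None,
    config: UnifyConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full five-step standardization; returns (unified, removals)."""
    cfg = config or UnifyConfig()
    table = adduct_table or default_adducts()
    kept, rem1 = quality_filter(records, compounds, table, cfg.ppm_max)
    merged, rem2 = merge_within_dataset(kept, cfg.intra_dataset_max_diff_pct)
    cleaned, rem3 = remove_trendline_outliers(
        merged, compounds, table, cfg.min_class_n, cfg.pi_level
    )
    unified = compute_unified_ccs(cleaned, cfg)
    removals = pd.concat([rem1, rem2, rem3], ignore_index=True)
    return unified, removals
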