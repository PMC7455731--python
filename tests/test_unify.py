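"""Standardization pipeline: quality check, merging, trend lines, confidence."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_records
from ccsatlas.adducts import PROTON_MASS
from ccsatlas.unify import (
    assign_confidence,
    compute_unified_ccs,
    max_diff_pct,
    merge_within_dataset,
    quality_filter,
    remove_trendline_outliers,
    unify_pipeline,
)


class TestQualityFilter:
    def test_large_ppm_error_removed(self, toy_compounds):
        rec = make_records([("C1", "[M+H]+", 150.0, "DS1", "DTIM")])
        theo = toy_compounds.set_index("id").loc["C1", "mass"] + PROTON_MASS
        rec.loc[0, "mz_reported"] = theo * (1 + 15e-6)  # 15 ppm off
        kept, removed = quality_filter(rec, toy_compounds)
        assert kept.empty
        assert removed["reason"].str.contains("10 ppm").all()

    def test_small_ppm_error_kept(self, toy_compounds):
        rec = make_records([("C1", "[M+H]+", 150.0, "DS1", "DTIM")])
        theo = toy_compounds.set_index("id").loc["C1", "mass"] + PROTON_MASS
        rec.loc[0, "mz_reported"] = theo * (1 + 5e-6)
        kept, removed = quality_filter(rec, toy_compounds)
        assert len(kept) == 1 and removed.empty

    def test_non_whitelist_adduct_removed(self, toy_compounds):
        rec = make_records([("C1", "[M+K]+", 150.0, "DS1", "DTIM")])
        kept, removed = quality_filter(rec, toy_compounds)
        assert kept.empty and "not whitelisted" in removed["reason"].iloc[0]

    def test_missing_structure_removed(self, toy_compounds):
        rec = make_records([("UNKNOWN", "[M+H]+", 150.0, "DS1", "DTIM")])
        kept, removed = quality_filter(rec, toy_compounds)
        assert kept.empty and "structure" in removed["reason"].iloc[0]

    def test_clean_simulator_batch_identity(self, clean_study):
        kept, removed = quality_filter(clean_study["records"], clean_study["compounds"])
        assert len(kept) == len(clean_study["records"]) and removed.empty


class TestMergeWithinDataset:
    def test_consistent_pair_averaged(self):
        rec = make_records(
            [("C1", "[M+H]+", 200.0, "DS1", "DTIM"), ("C1", "[M+H]+", 200.8, "DS1", "DTIM")]
        )
        assert max_diff_pct([200.0, 200.8]) == pytest.approx(0.399, abs=1e-3)
        merged, removed = merge_within_dataset(rec)
        assert len(merged) == 1 and removed.empty
        assert merged["ccs"].iloc[0] == pytest.approx(200.4)
        assert sorted(merged["source_record_ids"].iloc[0]) == ["R0000", "R0001"]

    def test_inconsistent_pair_removed(self):
        rec = make_records(
            [("C1", "[M+H]+", 200.0, "DS1", "DTIM"), ("C1", "[M+H]+", 201.2, "DS1", "DTIM")]
        )
        assert max_diff_pct([200.0, 201.2]) == pytest.approx(0.598, abs=1e-3)
        merged, removed = merge_within_dataset(rec)
        assert merged.empty and len(removed) == 2

    def test_singleton_passes_through(self):
        rec = make_records([("C1", "[M+H]+", 150.0, "DS1", "TWIM")])
        merged, removed = merge_within_dataset(rec)
        assert len(merged) == 1 and removed.empty
        assert merged["ccs"].iloc[0] == 150.0


def _pi_outlier_oracle(mz, ccs, level=0.99):
    """Independent OLS prediction-interval check on log-log axes."""
    x, y = np.log(mz), np.log(ccs)
    n = len(x)
    slope, intercept, *_ = stats.linregress(x, y)
    resid = y - (intercept + slope * x)
    s = np.sqrt(np.sum(resid**2) / (n - 2))
    t = stats.t.ppf((1 + level) / 2, n - 2)
    sxx = np.sum((x - x.mean()) ** 2)
    half = t * s * np.sqrt(1 + 1 / n + (x - x.mean()) ** 2 / sxx)
    return np.abs(resid) > half


def _trendline_fixture(n=30, displaced=None, noise=0.001, seed=1):
    rng = np.random.default_rng(seed)
    mz = np.linspace(120, 800, n)
    ccs = 8.5 * mz**0.52 * (1 + rng.normal(0, noise, n))
    if displaced is not None:
        ccs[displaced] *= 1.25
    compounds = pd.DataFrame(
        {
            "id": [f"C{i}" for i in range(n)],
            "name": [f"c{i}" for i in range(n)],
            "smiles": ["CCO"] * n,
            "mass": mz - PROTON_MASS,
            "superclass": ["ClassA"] * n,
            "parsed": True,
        }
    )
    records = make_records(
        [(f"C{i}", "[M+H]+", ccs[i], "DS1", "DTIM") for i in range(n)]
    )
    return compounds, records, mz, ccs


class TestTrendline:
    def test_displaced_point_removed_matches_oracle(self):
        compounds, records, mz, ccs = _trendline_fixture(displaced=13)
        kept, removed = remove_trendline_outliers(records, compounds)
        oracle = _pi_outlier_oracle(mz, ccs)
        assert list(removed["record_id"]) == [f"R{i:04d}" for i in np.where(oracle)[0]]
        assert list(removed["record_id"]) == ["R0013"]

    def test_small_class_untouched(self):
        compounds, records, *_ = _trendline_fixture(n=9, displaced=4)
        kept, removed = remove_trendline_outliers(records, compounds, min_class_n=10)
        assert removed.empty and len(kept) == 9

    def test_noise_free_class_zero_removals(self):
        compounds, records, *_ = _trendline_fixture(noise=0.0)
        kept, removed = remove_trendline_outliers(records, compounds)
        assert removed.empty


class TestUnifiedValue:
    def test_dtim_priority_mean(self):
        rec = make_records(
            [
                ("C1", "[M+H]+", 195.3, "DS1", "DTIM"),
                ("C1", "[M+H]+", 195.7, "DS2", "DTIM"),
                ("C1", "[M+H]+", 199.0, "DS3", "TWIM"),
            ]
        )
        uni = compute_unified_ccs(rec)
        assert uni["unified_ccs"].iloc[0] == pytest.approx(195.5)

    def test_plain_mean_without_dtim(self):
        rec = make_records(
            [("C1", "[M+H]+", 210.0, "DS1", "TWIM"), ("C1", "[M+H]+", 212.0, "DS2", "TIMS")]
        )
        uni = compute_unified_ccs(rec)
        assert uni["unified_ccs"].iloc[0] == pytest.approx(211.0)

    def test_singleton_identity(self):
        rec = make_records([("C1", "[M+H]+", 150.0, "DS1", "DTIM")])
        uni = compute_unified_ccs(rec)
        assert uni["unified_ccs"].iloc[0] == 150.0
        assert uni["level"].iloc[0] == "3"

    def test_bounded_by_sources_and_order_invariant(self, sim_study):
        rec = sim_study["records"].head(400)
        uni = compute_unified_ccs(rec)
        grouped = rec.groupby(["compound_id", "adduct"])["ccs"]
        lo, hi = grouped.min(), grouped.max()
        for _, row in uni.iterrows():
            key = (row["compound_id"], row["adduct"])
            assert lo[key] - 1e-9 <= row["unified_ccs"] <= hi[key] + 1e-9
        shuffled = rec.sample(frac=1.0, random_state=3)
        uni2 = compute_unified_ccs(shuffled)
        merged = uni.merge(uni2, on=["compound_id", "adduct"], suffixes=("", "_b"))
        assert np.allclose(merged["unified_ccs"], merged["unified_ccs_b"])


def _expected_level(n_datasets, n_dtim, diff):
    # independent restatement of the published cascade
    if n_datasets == 1:
        return "3"
    if n_dtim >= 2 and diff <= 1.0:
        return "1"
    if diff <= 3.0:
        return "2"
    return "Conflict"


class TestConfidenceCascade:
    def test_worked_examples(self):
        assert assign_confidence(2, 2, 0.8) == "1"
        assert assign_confidence(2, 1, 2.0) == "2"
        assert assign_confidence(2, 0, 3.5) == "Conflict"
        assert assign_confidence(1, 1, 0.0) == "3"

    def test_exhaustive_decision_grid(self):
        diffs = [0.0, 0.5, 1.0, 1.0001, 2.0, 3.0, 3.0001, 5.0, 50.0]
        for n_datasets in range(1, 6):
            for n_dtim in range(0, n_datasets + 1):
                for diff in diffs:
                    got = assign_confidence(n_datasets, n_dtim, diff)
                    assert got == _expected_level(n_datasets, n_dtim, diff), (
                        n_datasets, n_dtim, diff)

    def test_dtim_pair_with_moderate_diff_falls_to_level2(self):
        assert assign_confidence(2, 2, 2.0) == "2"


class TestPipeline:
    def test_record_conservation(self, sim_study):
        records, compounds = sim_study["records"], sim_study["compounds"]
        unified, removals = unify_pipeline(records, compounds)
        accounted = removals["record_id"].tolist()
        for srcs in unified["source_record_ids"]:
            accounted.extend(srcs)
        assert sorted(accounted) == sorted(records["record_id"])

    def test_clean_study_recovers_truth_exactly(self, clean_study):
        unified, removals = unify_pipeline(clean_study["records"], clean_study["compounds"])
        assert removals.empty
        truth = clean_study["truth"].set_index(["compound_id", "adduct"])["ccs_true"]
        for _, row in unified.iterrows():
            assert row["unified_ccs"] == pytest.approx(
                truth[(row["compound_id"], row["adduct"])], rel=1e-12
            )
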