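"""Multi-dimensional annotation: trapezoid CCS score, reverse dot-product, ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccsatlas.adducts import PROTON_MASS
from ccsatlas.annotate import (
    Feature,
    MatchTolerances,
    ccs_score,
    delta_rela,
    integrated_score,
    match_mz,
    msms_score,
    parse_feature_id,
    rank_candidates,
    rescale_scores,
)
from ccsatlas.chemio import Spectrum


class TestDeltaRela:
    @pytest.mark.parametrize(
        "pred, exp, expected", [(204.0, 200.0, 2.0), (200.0, 200.0, 0.0), (190.0, 200.0, 5.0)]
    )
    def test_worked_values(self, pred, exp, expected):
        assert delta_rela(pred, exp) == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            delta_rela(-1.0, 200.0)


def _trapezoid_oracle(d, lo=2.0, hi=4.0):
    if d < lo:
        return 1.0
    if d > hi:
        return 0.0
    return (hi - d) / (hi - lo)


class TestCcsScore:
    @pytest.mark.parametrize(
        "delta, expected", [(1.0, 1.0), (2.0, 1.0), (3.0, 0.5), (4.0, 0.0), (5.0, 0.0)]
    )
    def test_worked_values(self, delta, expected):
        assert ccs_score(delta) == pytest.approx(expected)

    def test_exhaustive_grid_matches_closed_form(self):
        for d in np.arange(0.0, 6.001, 0.01):
            assert ccs_score(float(d)) == pytest.approx(_trapezoid_oracle(d))

    def test_boundary_continuity(self):
        eps = 1e-9
        assert ccs_score(2.0 - eps) == pytest.approx(ccs_score(2.0 + eps), abs=1e-6)
        assert ccs_score(4.0 - eps) == pytest.approx(ccs_score(4.0 + eps), abs=1e-6)

    def test_nonincreasing_in_delta(self):
        grid = np.linspace(0, 8, 400)
        scores = [ccs_score(float(d)) for d in grid]
        assert all(a >= b - 1e-12 for a, b in zip(scores, scores[1:]))

    def test_equal_tolerances_degenerate_to_step(self):
        tol = MatchTolerances(tol_min_pct=3.0, tol_max_pct=3.0)
        assert ccs_score(2.9, tol) == 1.0
        assert ccs_score(3.0, tol) == 1.0
        assert ccs_score(3.1, tol) == 0.0


class TestIntegratedScore:
    @pytest.mark.parametrize(
        "s_ccs, s_msms, expected", [(1, 1, 1.0), (1, 0, 0.3), (0, 1, 0.7), (0.5, 0.5, 0.5)]
    )
    def test_worked_values(self, s_ccs, s_msms, expected):
        assert integrated_score(s_ccs, s_msms) == pytest.approx(expected)

    def test_bad_weights_rejected_unless_overridden(self):
        tol = MatchTolerances(w_ccs=0.5, w_msms=0.7)
        with pytest.raises(ValueError):
            integrated_score(1, 1, tol)
        assert integrated_score(1, 1, tol, allow_unnormalized=True) == pytest.approx(1.2)

    @settings(deadline=None, max_examples=50)
    @given(
        a=st.floats(0, 1), b=st.floats(0, 1),
        da=st.floats(0, 0.5), db=st.floats(0, 0.5),
    )
    def test_monotone_in_each_component(self, a, b, da, db):
        base = integrated_score(a, b)
        assert integrated_score(min(a + da, 1), b) >= base - 1e-12
        assert integrated_score(a, min(b + db, 1)) >= base - 1e-12


class TestMsmsScore:
    def test_identical_spectra_score_one(self):
        s = Spectrum([[100.0, 50.0], [150.0, 100.0], [200.0, 10.0]])
        assert msms_score(s, s) == pytest.approx(1.0)

    def test_reference_absent_scores_zero(self):
        exp = Spectrum([[100.0, 50.0]])
        ref = Spectrum([[300.0, 10.0], [400.0, 20.0]])
        assert msms_score(exp, ref) == 0.0

    def test_worked_three_peak_case_matches_cosine_oracle(self):
        ref = Spectrum([[100.0, 100.0], [150.0, 50.0], [200.0, 10.0]])
        exp = Spectrum([[100.0, 100.0], [150.0, 50.0]])
        # independent weighted-cosine oracle over reference peaks
        w_ref = np.sqrt([100.0, 50.0, 10.0])
        w_exp = np.sqrt([100.0, 50.0, 0.0])
        expected = (w_ref @ w_exp) ** 2 / ((w_ref @ w_ref) * (w_exp @ w_exp))
        assert msms_score(exp, ref) == pytest.approx(expected)

    def test_experimental_only_peaks_ignored(self):
        ref = Spectrum([[100.0, 100.0], [150.0, 50.0]])
        exp = Spectrum([[100.0, 100.0], [150.0, 50.0]])
        noisy = Spectrum([[100.0, 100.0], [150.0, 50.0], [500.0, 999.0]])
        assert msms_score(noisy, ref) == pytest.approx(msms_score(exp, ref))

    def test_simulator_clean_copies_score_one(self, clean_study):
        refs, exps = clean_study["ref_spectra"], clean_study["exp_spectra"]
        for r, e in zip(refs[:10], exps[:10]):
            assert msms_score(e, r) == pytest.approx(1.0, abs=1e-9)


class TestRescale:
    def test_three_candidate_toy_set(self):
        out = rescale_scores([12.0, 7.0, 2.0])
        assert out == pytest.approx([1.0, 0.5, 0.0])

    def test_constant_scores_map_to_one(self):
        assert rescale_scores([3.0, 3.0]) == pytest.approx([1.0, 1.0])


class TestFeatureId:
    def test_roundtrip_convention(self):
        f = Feature(mz=384.1129, rt=767.0, ccs=188.9)
        assert f.feature_id == "M384T767C189"
        assert parse_feature_id(f.feature_id) == (384, 767, 189)

    def test_malformed_id_rejected(self):
        with pytest.raises(ValueError):
            parse_feature_id("X1T2C3")


def _db(rows):
    return pd.DataFrame(rows, columns=["id", "name", "mass", "ccs", "ccs_source"])


class TestMatchMz:
    def test_exact_hit_zero_ppm(self):
        db = _db([("A", "a", 180.06339, 140.0, "unified")])
        feat = Feature(mz=180.06339 + PROTON_MASS, rt=0, ccs=140.0)
        cand = match_mz(feat, db)
        assert list(cand["id"]) == ["A"]
        assert cand["ppm_error"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_thirty_ppm_excluded_at_default_tolerance(self):
        mass = 180.06339
        db = _db([("A", "a", mass * (1 + 30e-6), 140.0, "unified")])
        feat = Feature(mz=mass + PROTON_MASS, rt=0, ccs=140.0)
        assert match_mz(feat, db).empty

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError):
            match_mz(Feature(mz=100, rt=0, ccs=120), pd.DataFrame())

    def test_planted_duplicates_match_linear_scan_oracle(self):
        rng = np.random.default_rng(4)
        masses = rng.uniform(100, 500, 200)
        db = _db([(f"C{i}", "x", m, 150.0, "unified") for i, m in enumerate(masses)])
        target = masses[17]
        for j, ppm in enumerate([5e-6, -20e-6, 40e-6]):
            db.loc[len(db)] = (f"P{j}", "planted", target * (1 + ppm), 150.0, "unified")
        feat = Feature(mz=target + PROTON_MASS, rt=0, ccs=150.0)
        cand = match_mz(feat, db)
        theo = db["mass"] + PROTON_MASS
        oracle = db[np.abs((feat.mz - theo) / theo * 1e6) <= 25].copy()
        assert sorted(cand["id"]) == sorted(oracle["id"])


class TestRankCandidates:
    def _benchmark(self):
        true_ccs = 200.0
        mass = 300.0
        db = _db(
            [("TRUE", "planted", mass, true_ccs, "unified")]
            + [(f"D{i}", "decoy", mass * (1 + 3e-6 * (i - 3)), true_ccs * (1 + 0.10 + 0.01 * i), "predicted-level-4")
               for i in range(6)]
        )
        ref = Spectrum([[120.0, 100.0], [180.0, 40.0]])
        feat = Feature(mz=mass + PROTON_MASS, rt=10, ccs=true_ccs, spectrum=ref)
        return feat, db, {"TRUE": ref}

    def test_planted_truth_ranks_first(self):
        feat, db, refs = self._benchmark()
        res = rank_candidates(feat, db, reference_spectra=refs)
        assert res.candidates["id"].iloc[0] == "TRUE"
        assert res.candidates["rank"].iloc[0] == 1
        assert res.candidates["s_integrated"].iloc[0] == pytest.approx(1.0)

    def test_disabling_ccs_never_decreases_candidates(self):
        feat, db, refs = self._benchmark()
        with_ccs = rank_candidates(feat, db, reference_spectra=refs)
        without = rank_candidates(feat, db, use_ccs=False, reference_spectra=refs)
        assert without.n_ranked >= with_ccs.n_ranked
        assert with_ccs.n_after_ccs <= with_ccs.n_mz_matched

    def test_candidates_beyond_tolmax_removed(self):
        feat, db, refs = self._benchmark()
        res = rank_candidates(feat, db, reference_spectra=refs)
        assert (res.candidates["delta_rela_pct"] <= 4.0 + 1e-9).all()

    def test_missing_spectrum_falls_back_to_ccs_weight_one(self):
        feat, db, _ = self._benchmark()
        feat.spectrum = None
        res = rank_candidates(feat, db, reference_spectra=None)
        assert res.used_ccs_fallback
        best = res.candidates.iloc[0]
        assert best["s_integrated"] == pytest.approx(best["s_ccs"])

    def test_external_scores_rescaled_before_integration(self):
        feat, db, _ = self._benchmark()
        ext = {"TRUE": 500.0, "D0": 100.0, "D1": 300.0}
        res = rank_candidates(feat, db, external_msms_scores=ext)
        got = res.candidates.set_index("id")["s_msms"]
        assert got["TRUE"] == pytest.approx(1.0)

    def test_no_dimension_enabled_rejected(self):
        feat, db, _ = self._benchmark()
        with pytest.raises(ValueError):
            rank_candidates(feat, db, use_ccs=False, use_msms=False)
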