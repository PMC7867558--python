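"""ROI aggregation, signed-rank test, Hodges-Lehmann CI, crossover analysis."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import tailored_tacs as tt
from tailored_tacs.synthetic_data import DEFAULT_MONTAGE
from tailored_tacs.trial_stats import DEFAULT_ROIS, signed_rank_test


def enumerate_p(d):
    """Independent oracle: two-sided p by full 2^n sign enumeration."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = d.size
    n_le = n_ge = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        n_le += w <= w_obs + 1e-9
        n_ge += w >= w_obs - 1e-9
    return min(1.0, 2.0 * min(n_le, n_ge) / 2**n)


class TestRoiBandPower:
    def test_mean_of_three(self):
        table = pd.DataFrame(
            {"theta": [10.0, 20.0, 30.0]},
            index=pd.Index(["Fp2", "F8", "F4"], name="channel"),
        )
        scheme = tt.ROIScheme({"right_frontal": ("Fp2", "F8", "F4")})
        roi = tt.roi_band_power(table, scheme)
        assert roi.loc["right_frontal", "theta"] == pytest.approx(20.0)

    def test_uniform_table_constancy(self):
        table = pd.DataFrame(
            7.5, index=pd.Index(DEFAULT_MONTAGE, name="channel"),
            columns=["delta", "theta"],
        )
        roi = tt.roi_band_power(table)
        assert np.allclose(roi.to_numpy(), 7.5)
        assert set(roi.index) == {
            "left_frontal", "right_frontal", "left_motor",
            "right_motor", "left_parietal", "right_parietal",
        }

    def test_matches_brute_force(self, rng):
        table = pd.DataFrame(
            rng.uniform(0, 40, size=(32, 5)),
            index=pd.Index(DEFAULT_MONTAGE, name="channel"),
            columns=["delta", "theta", "alpha1", "alpha2", "beta"],
        )
        roi = tt.roi_band_power(table)
        for name, electrodes in DEFAULT_ROIS.rois.items():
            manual = table.loc[list(electrodes)].mean(axis=0)
            np.testing.assert_allclose(roi.loc[name], manual)

    def test_missing_electrode_named_in_error(self):
        table = pd.DataFrame(
            {"theta": [1.0]}, index=pd.Index(["Fp2"], name="channel")
        )
        with pytest.raises(ValueError, match="F8"):
            tt.roi_band_power(table, tt.ROIScheme({"rf": ("Fp2", "F8")}))

    def test_roi_sets_disjoint_enforced(self):
        with pytest.raises(ValueError, match="overlap"):
            tt.ROIScheme({"a": ("C3", "C4"), "b": ("C4", "Cz")})


class TestSignedRank:
    def test_all_positive_six(self):
        assert signed_rank_test(np.arange(1.0, 7.0))[2] == pytest.approx(
            0.03125, abs=1e-12
        )

    def test_identical_samples_degenerate(self):
        res = tt.paired_wilcoxon(np.arange(5.0), np.arange(5.0))
        assert res.degenerate and res.p == 1.0

    @given(st.integers(0, 2**31 - 1), st.integers(3, 10))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_exact_p_equals_enumeration(self, seed, n):
        d = np.random.default_rng(seed).normal(size=n)
        _, _, p, method = signed_rank_test(d)
        assert method == "exact"
        assert p == pytest.approx(enumerate_p(d), abs=1e-12)

    @given(st.integers(0, 2**31 - 1), st.integers(4, 12))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_symmetry_in_argument_order(self, seed, n):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=n), r.normal(size=n)
        assert tt.paired_wilcoxon(x, y).p == pytest.approx(
            tt.paired_wilcoxon(y, x).p, abs=1e-12
        )

    def test_matches_scipy_exact(self, rng):
        for _ in range(20):
            d = rng.normal(size=int(rng.integers(6, 20)))
            p_ours = signed_rank_test(d)[2]
            p_scipy = stats.wilcoxon(d, method="exact").pvalue
            assert p_ours == pytest.approx(p_scipy, abs=1e-12)

    def test_tie_corrected_approx_matches_scipy(self, rng):
        d = rng.integers(-3, 4, size=40).astype(float)
        d = d[d != 0]
        p_ours = signed_rank_test(d)[2]
        p_scipy = stats.wilcoxon(
            d, method="approx", correction=False
        ).pvalue
        assert p_ours == pytest.approx(p_scipy, rel=1e-9)

    def test_monotone_shift_decreases_one_sided_evidence(self, rng):
        # adding a positive constant to the differences never increases
        # the positive-direction one-sided p
        d = rng.normal(size=12)

        def one_sided_ge(dd):
            dd = dd[dd != 0]
            ranks = stats.rankdata(np.abs(dd))
            w = ranks[dd > 0].sum()
            from tailored_tacs.trial_stats import _exact_null_counts

            counts = _exact_null_counts(dd.size)
            return counts[int(round(w)):].sum() / counts.sum()

        base = one_sided_ge(d)
        shifted = one_sided_ge(d + 1.0)
        assert shifted <= base + 1e-12

    def test_zero_differences_dropped(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 1.0, 1.0, 1.0])
        res = tt.paired_wilcoxon(x, y)  # one zero diff dropped
        assert res.statistic == 6.0  # remaining diffs 1,2,3 all positive


class TestHodgesLehmann:
    def test_two_point_walsh(self):
        est, lo, hi = tt.hodges_lehmann_ci(np.array([1.0, 3.0]))
        assert est == pytest.approx(2.0)
        assert lo <= est <= hi

    def test_constant_differences(self):
        est, lo, hi = tt.hodges_lehmann_ci(np.full(6, 2.5))
        assert (est, lo, hi) == (2.5, 2.5, 2.5)

    def test_matches_brute_force_n8(self, rng):
        d = rng.normal(size=8)
        walsh = sorted(
            (d[i] + d[j]) / 2 for i in range(8) for j in range(i, 8)
        )
        assert len(walsh) == 36
        est, lo, hi = tt.hodges_lehmann_ci(d)
        assert est == pytest.approx(np.median(walsh), abs=1e-12)
        assert lo in walsh and hi in walsh

    def test_needs_two_differences(self):
        with pytest.raises(ValueError):
            tt.hodges_lehmann_ci(np.array([1.0]))

    def test_ci_covers_truth_at_nominal_rate(self, rng):
        hits = 0
        for _ in range(300):
            d = rng.normal(loc=0.7, size=15)
            _, lo, hi = tt.hodges_lehmann_ci(d, level=0.95)
            hits += lo <= 0.7 <= hi
        assert 0.90 <= hits / 300 <= 0.99


class TestCrossoverAnalysis:
    def test_missing_cell_contrast_skipped_with_warning(self, caplog):
        table = pd.DataFrame(
            {
                "subject": ["S1", "S2", "S3"],
                "sequence": ["tACS-first"] * 3,
                "timepoint": ["T0"] * 3,
                "condition": [""] * 3,
                "measure": ["VAS"] * 3,
                "value": [5.0, 6.0, 7.0],
            }
        )
        with caplog.at_level("WARNING", logger="tailored_tacs"):
            results = tt.crossover_analysis(table)
        assert results == []
        assert "skipping" in caplog.text

    def test_planted_tacs_effect_detected_with_high_power(self):
        spec = tt.OutcomeSpec(
            n_subjects=14, measures={"VAS": (0, 10)},
            effects={"VAS": {("tACS", "T1"): -2.0}}, noise_sd=1.0,
        )
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            res = {r.contrast: r for r in
                   tt.crossover_analysis(tt.generate_outcomes(spec, seed=rep))}
            hits += res["T0 vs tACS-T1"].p < 0.05
        assert hits / n_rep >= 0.80

    def test_complete_case_pairing(self):
        rows = []
        for s, v0, v1 in [("S1", 5, 3), ("S2", 6, 4), ("S3", 7, 4)]:
            rows.append((s, "tACS-first", "T0", "", "VAS", float(v0)))
            rows.append((s, "tACS-first", "T1", "tACS", "VAS", float(v1)))
        # S4 has only baseline: must be excluded from the pairing
        rows.append(("S4", "tACS-first", "T0", "", "VAS", 9.0))
        table = pd.DataFrame(
            rows, columns=["subject", "sequence", "timepoint", "condition",
                           "measure", "value"],
        )
        res = {r.contrast: r for r in tt.crossover_analysis(table)}
        assert res["T0 vs tACS-T1"].n_pairs == 3
        assert res["T0 vs tACS-T1"].estimate > 0  # T0 minus T1 positive

    def test_results_frame_columns(self):
        spec = tt.OutcomeSpec(n_subjects=8, measures={"VAS": (0, 10)})
        frame = tt.results_to_frame(
            tt.crossover_analysis(tt.generate_outcomes(spec, seed=0))
        )
        assert list(frame.columns) == [
            "contrast", "measure", "n", "statistic", "p",
            "estimate", "ci_low", "ci_high", "method",
        ]
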