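import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import limbkine as lk
from limbkine.cohort_stats import (_approx_signed_rank_p,
                                   _exact_signed_rank_p)


def features_frame(rows):
    cols = ["participant_id", "task", "leg", "dominant", "trial_index",
            "parameter", "value"]
    return pd.DataFrame(rows, columns=cols)


class TestCohortSummary:
    def test_quantile_oracle(self):
        """{1..5}: median 3, IQR 2 (type-7 quantiles), %IQR 66.7."""
        rows = [("P1", "TT", "right", True, k, "angle", v)
                for k, v in enumerate([1, 2, 3, 4, 5], start=1)]
        out = lk.cohort_summary(features_frame(rows))
        row = out.iloc[0]
        assert row["median"] == 3.0
        assert row["iqr"] == 2.0
        assert row["pct_iqr"] == pytest.approx(100 * 2 / 3)

    def test_constant_values_have_zero_iqr(self):
        rows = [("P1", "TT", "right", True, k, "angle", 4.0) for k in range(1, 5)]
        out = lk.cohort_summary(features_frame(rows))
        assert out.iloc[0]["iqr"] == 0.0
        assert out.iloc[0]["pct_iqr"] == 0.0

    def test_reference_ratio(self):
        """median 2.8, IQR 0.5 gives the printed 17.9 %IQR."""
        rows = ([("P1", "TT", "right", True, k, "frequency", 2.8 + d)
                 for k, d in enumerate([-0.3, -0.25, 0.0, 0.25, 0.3], 1)])
        out = lk.cohort_summary(features_frame(rows))
        assert round(out.iloc[0]["pct_iqr"], 1) == 17.9

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        rows = [("P1", "TT", "right", True, k, "angle", v)
                for k, v in enumerate(rng.normal(16, 2, 5), 1)]
        a = lk.cohort_summary(features_frame(rows))
        b = lk.cohort_summary(features_frame(rows[::-1]))
        pd.testing.assert_frame_equal(a, b)

    def test_empty_group_warns_and_is_omitted(self):
        rows = [("P1", "TT", "right", True, 1, "angle", np.nan)]
        with pytest.warns(UserWarning, match="omitted"):
            out = lk.cohort_summary(features_frame(rows))
        assert len(out) == 0


class TestClassifiers:
    @pytest.mark.parametrize("pct,expected", [
        (17.9, "small"), (29.99, "small"), (30.0, "moderate"),
        (59.9, "moderate"), (60.0, "high"), (119.9, "high"),
        (120.0, "very_high"), (182.0, "very_high"),
    ])
    def test_pct_iqr_bins(self, pct, expected):
        assert lk.classify_pct_iqr(pct) == expected

    def test_pct_iqr_negative_rejected(self):
        with pytest.raises(ValueError):
            lk.classify_pct_iqr(-1.0)

    @pytest.mark.parametrize("r2,expected", [
        (0.0, "negligible"), (0.09, "negligible"), (0.10, "weak"),
        (0.15, "weak"), (0.19, "moderate"), (0.48, "moderate"),
        (0.49, "strong"), (0.80, "very_strong"), (1.0, "very_strong"),
    ])
    def test_r2_bins(self, r2, expected):
        assert lk.classify_r2(r2) == expected

    def test_r2_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lk.classify_r2(1.2)


class TestWilcoxon:
    def test_all_positive_six_pairs_exact_p(self):
        """Six positive differences: two-sided exact p = 2/2^6 = 0.03125."""
        x = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        res = lk.wilcoxon_signed_rank(x, np.zeros(6))
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 64)
        assert res.statistic == 21.0

    def test_identical_samples_undefined(self):
        x = np.array([1.0, 2.0, 3.0])
        res = lk.wilcoxon_signed_rank(x, x)
        assert res.method == "undefined"
        assert np.isnan(res.p_value)

    def test_fewer_than_two_pairs_rejected(self):
        with pytest.raises(ValueError):
            lk.wilcoxon_signed_rank([1.0], [0.0])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_scipy_exact_on_tie_free_data(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 20))
        d = rng.normal(0.2, 1.0, n)
        d = d[d != 0]
        ours = lk.wilcoxon_signed_rank(d, np.zeros_like(d))
        ref = stats.wilcoxon(d, mode="exact")
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_vs_normal_approximation_at_n25(self):
        """The two p-value routes agree to |dp| < 0.01 at n = 25."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            d = rng.normal(0.1, 1.0, 25)
            ranks = stats.rankdata(np.abs(d))
            w = float(ranks[d > 0].sum())
            assert abs(_exact_signed_rank_p(w, ranks)
                       - _approx_signed_rank_p(w, ranks)) < 0.01

    def test_handles_midranked_ties_exactly(self):
        d = np.array([1.0, 1.0, -1.0, 2.0, 3.0, 3.0, 4.0])
        res = lk.wilcoxon_signed_rank(d, np.zeros_like(d))
        assert res.method == "exact"
        assert 0.0 < res.p_value <= 1.0


class TestDominanceTests:
    def test_participant_level_pairing(self):
        rows = []
        rng = np.random.default_rng(0)
        for p in range(8):
            base = rng.normal(16, 1)
            for k in range(1, 6):
                rows.append((f"P{p}", "TT", "right", True, k, "angle",
                             base + rng.normal(0, 0.5)))
                rows.append((f"P{p}", "TT", "left", False, k, "angle",
                             base + rng.normal(0, 0.5)))
        out = lk.dominance_tests(features_frame(rows))
        assert len(out) == 1
        assert out.iloc[0]["n_pairs"] == 8
        assert out.iloc[0]["method"] == "exact"

    def test_systematic_shift_detected(self):
        rows = []
        rng = np.random.default_rng(1)
        for p in range(12):
            base = rng.normal(16, 1)
            for k in range(1, 6):
                rows.append((f"P{p}", "TT", "right", True, k, "angle",
                             base + 3.0 + rng.normal(0, 0.2)))
                rows.append((f"P{p}", "TT", "left", False, k, "angle",
                             base + rng.normal(0, 0.2)))
        out = lk.dominance_tests(features_frame(rows))
        assert bool(out.iloc[0]["significant_at_0_05"])


class TestIntervalMedians:
    def _cycles(self, trial_rows):
        cols = ["participant_id", "task", "leg", "dominant", "trial_index",
                "interval_index", "angle", "frequency"]
        return pd.DataFrame(trial_rows, columns=cols)

    def test_uniform_trial_gives_identical_rows(self):
        rows = [("P1", "TT", "right", True, 1, i, 16.0, 2.8)
                for i in (1, 2, 3, 4) for _ in range(10)]
        out = lk.interval_medians(self._cycles(rows))
        assert len(out) == 4
        assert np.allclose(out["angle"], 16.0)
        assert np.allclose(out["frequency"], 2.8)
        assert np.all(out["n_cycles"] == 10)

    def test_missing_interval_emits_nan(self):
        rows = [("P1", "TT", "right", True, 1, 1, 16.0, 2.8)]
        out = lk.interval_medians(self._cycles(rows))
        assert len(out) == 4
        assert out.loc[out["interval"] == 3, "angle"].isna().all()
        assert (out.loc[out["interval"] == 3, "n_cycles"] == 0).all()

    def test_decrement_visible_in_interval_medians(self):
        """On default synthetic trials, interval 1 angles exceed interval 4
        angles in nearly every trial."""
        wins = 0
        total = 0
        for seed in range(20):
            rec, _ = lk.generate_tt_trial(lk.TTGenParams(), seed=seed)
            cs = lk.assign_intervals(lk.segment_trial(rec))
            tab = lk.cycle_feature_table(rec, cs)
            im = lk.interval_medians(tab)
            a1 = im.loc[im["interval"] == 1, "angle"].iloc[0]
            a4 = im.loc[im["interval"] == 4, "angle"].iloc[0]
            total += 1
            wins += bool(a1 > a4)
        assert wins >= 0.95 * total
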