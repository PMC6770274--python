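import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mtfrag.cohort import (
    dichotomize_by_ctdna,
    group_series,
    pearson_correlation,
    track_patient,
    welch_t_test,
)
from mtfrag.simulate import (
    simulate_burden_cohort,
    simulate_group_cohort,
    simulate_longitudinal_series,
)


class TestWelch:
    def test_identical_groups_give_no_evidence(self):
        cmp = welch_t_test([1, 2, 3], [1, 2, 3])
        assert cmp.t_statistic == 0.0
        assert cmp.p_value == 1.0

    def test_closed_form_small_example(self):
        # means 2 vs 5, both variances 1: t = -3/sqrt(2/3) = -3.674, Welch df = 4
        cmp = welch_t_test([1, 2, 3], [4, 5, 6])
        assert cmp.t_statistic == pytest.approx(-3.674, abs=0.001)
        assert cmp.df == pytest.approx(4.0)
        assert cmp.p_value == pytest.approx(0.0213, abs=0.0005)

    def test_symmetric_up_to_sign(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 12), rng.normal(1, 2, 7)
        ab, ba = welch_t_test(a, b), welch_t_test(b, a)
        assert ab.t_statistic == pytest.approx(-ba.t_statistic)
        assert ab.p_value == pytest.approx(ba.p_value)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [2.0, 3.0])

    def test_cancer_vs_healthy_group_sizes_detectable(self):
        # group parameters of the plasma cohort (46 cancer vs 4 healthy)
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            cancer = rng.normal(109.15, 15, 46)
            healthy = rng.normal(142.62, 10, 4)
            hits += welch_t_test(cancer, healthy).p_value < 0.05
        assert hits >= 18


class TestPearson:
    def test_perfect_linear_relations(self):
        assert pearson_correlation([1, 2, 3], [2, 4, 6]).r == pytest.approx(1.0)
        assert pearson_correlation([1, 2, 3], [3, 2, 1]).r == pytest.approx(-1.0)

    def test_noisy_negative_slope_detected_across_seeds(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0, 10, 16)
            y = -2 * x + rng.normal(0, 1, 16)
            res = pearson_correlation(x, y)
            assert res.r < -0.9 and res.p_value < 0.05

    def test_missing_values_dropped_pairwise(self):
        res = pearson_correlation([1, 2, 3, np.nan, 5], [2, 4, 6, 8, np.nan])
        assert res.n == 3
        assert res.r == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    @given(
        scale=st.floats(min_value=0.1, max_value=50),
        shift=st.floats(min_value=-100, max_value=100),
    )
    def test_r_invariant_to_positive_affine_transform(self, scale, shift):
        x = np.array([1.0, 2.0, 4.0, 7.0, 11.0, 12.0])
        y = np.array([5.0, 3.0, 6.0, 2.0, 1.0, 4.0])
        base = pearson_correlation(x, y).r
        assert pearson_correlation(scale * x + shift, y).r == pytest.approx(base, abs=1e-9)


class TestDichotomy:
    def test_strict_threshold_split(self):
        df = pd.DataFrame({"ctdna_percent": [4.0, 6.0], "mean_mt_length": [160.0, 150.0]})
        high, low, cmp = dichotomize_by_ctdna(df)
        assert len(high) == 1 and len(low) == 1
        assert cmp is None  # too small for a test

    def test_all_below_threshold_flagged(self):
        df = pd.DataFrame({"ctdna_percent": [1.0, 2.0, 3.0], "mean_mt_length": [160, 161, 162]})
        high, low, cmp = dichotomize_by_ctdna(df)
        assert len(high) == 0 and cmp is None

    def test_high_burden_group_has_shorter_mt_fragments(self):
        # group means from the liver-cancer dichotomy (153.62 vs 164.36, sd 6, n 8/8);
        # power oracle: noncentral t with ncp = (164.36-153.62)/6 * sqrt(8/2) ~ 3.58,
        # per-seed power ~ 0.91, so require at least the 0.001-quantile of Bin(20, power)
        from scipy import stats as sps

        ncp = (164.36 - 153.62) / 6 * np.sqrt(8 / 2)
        crit = sps.t.ppf(0.975, df=14)
        power = sps.nct.sf(crit, df=14, nc=ncp)
        min_hits = int(sps.binom.ppf(0.001, 20, power))
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(
                {
                    "ctdna_percent": np.r_[rng.uniform(6, 30, 8), rng.uniform(0, 4, 8)],
                    "mean_mt_length": np.r_[rng.normal(153.62, 6, 8), rng.normal(164.36, 6, 8)],
                }
            )
            high, low, cmp = dichotomize_by_ctdna(df)
            assert len(high) == 8 and len(low) == 8
            assert cmp.mean_a < cmp.mean_b  # shorter mt-cfDNA in the high-burden group
            hits += cmp.p_value < 0.05
        assert hits >= min_hits


class TestLongitudinal:
    def test_rise_then_fall_flags_reversal(self):
        df = simulate_longitudinal_series(seed=0)
        series = track_patient(df)
        assert series.directions == (1, -1, -1)
        assert series.has_reversal

    def test_monotone_series_has_no_reversal(self):
        df = simulate_longitudinal_series(seed=0, mt_lengths=(150, 145, 140, 130),
                                          states=("s", "s", "s", "s"))
        assert not track_patient(df).has_reversal

    def test_directions_follow_sign_of_noise(self):
        base = simulate_longitudinal_series(seed=0, mt_lengths=(150.0, 150.0), states=("s", "s"))
        for eps in (0.5, -0.5):
            df = base.copy()
            df.loc[df["timepoint"] == 1, "mean_mt_length"] += eps
            assert track_patient(df).directions == (int(np.sign(eps)),)

    def test_duplicate_timepoint_rejected(self):
        df = simulate_longitudinal_series(seed=0)
        df.loc[df.index[-1], "timepoint"] = 2
        with pytest.raises(ValueError, match="duplicate"):
            track_patient(df)


class TestCohortSimulators:
    def test_group_cohort_shapes_and_ordering(self):
        df = simulate_group_cohort(seed=1)
        g = group_series(df)
        assert len(g["cancer"]) == 46 and len(g["healthy"]) == 4
        assert g["cancer"].mean() < g["healthy"].mean()

    def test_burden_cohort_declines_with_tumor_size_across_seeds(self):
        # the end-to-end inverse-correlation property
        hits = 0
        for seed in range(20):
            df = simulate_burden_cohort(seed=seed)
            res = pearson_correlation(df["mean_mt_length"], df["tumor_size"])
            hits += (res.r < 0) and (res.p_value < 0.05)
        assert hits >= 18

    def test_burden_cohort_has_missing_ctdna_annotations(self):
        df = simulate_burden_cohort(seed=3)
        assert df["ctdna_percent"].isna().sum() == 4
        res = pearson_correlation(df["mean_mt_length"], df["ctdna_percent"])
        assert res.n == 12
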