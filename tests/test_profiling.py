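import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mtfrag.profiling import (
    SizeProfile,
    detect_periodicity,
    mean_length,
    modal_length,
    normalized_mt_abundance,
    size_histogram,
)
from mtfrag.simulate import demo_models, simulate_fragments, demo_config
from mtfrag.sizemodels import draw_fragment_lengths


def profile_from(counts: dict[int, int]) -> SizeProfile:
    lengths = np.repeat(list(counts.keys()), list(counts.values()))
    return SizeProfile.from_lengths(lengths)


class TestHistogramSummaries:
    def test_counts_and_mode(self):
        p = profile_from({166: 100, 144: 80})
        assert p.n_total == 180
        assert modal_length(p) == 166

    def test_mode_tie_takes_smallest_length(self):
        assert modal_length(profile_from({169: 5, 144: 5})) == 144
        assert modal_length(profile_from({169: 6, 144: 5})) == 169

    def test_mean(self):
        assert mean_length(profile_from({100: 1, 200: 1})) == 150.0
        assert mean_length(profile_from({77: 12})) == 77.0

    def test_windowed_mean_excludes_outside_lengths(self):
        p = profile_from({100: 1, 200: 1, 900: 2})
        assert mean_length(p, window=(30, 500)) == 150.0

    def test_empty_profile_flagged_undefined(self):
        p = SizeProfile.from_lengths([])
        assert not p.defined
        assert modal_length(p) is None
        assert mean_length(p) is None

    def test_empty_window_returns_none(self):
        assert mean_length(profile_from({100: 5}), window=(300, 400)) is None


class TestSelectionAndNormalization:
    def test_histogram_selects_genome_and_compartment(self, contig_index):
        cfg = demo_config(seed=21, n_nuclear=5_000, n_mito_graft=500, n_mito_host=300)
        frags, _ = simulate_fragments(cfg, contig_index)
        prof = size_histogram(frags, genome="host", compartment="mito")
        assert prof.n_total == (frags["genome"].eq("host") & frags["compartment"].eq("mito")).sum()

    def test_profile_totals_conserve_fragment_count(self, contig_index):
        cfg = demo_config(seed=22, n_nuclear=5_000, n_mito_graft=500, n_mito_host=300, ambiguous_fraction=0.01)
        frags, _ = simulate_fragments(cfg, contig_index)
        keep = frags[~frags["ambiguous"]]
        total = sum(
            size_histogram(keep, genome=g, compartment=c).n_total
            for g in ("graft", "host")
            for c in ("nuclear", "mito")
        )
        assert total == len(keep)

    def test_normalized_mt_abundance(self):
        assert normalized_mt_abundance(0, 1000) == 0.0
        assert normalized_mt_abundance(10, 1000) == 0.01
        with pytest.raises(ValueError):
            normalized_mt_abundance(5, 0)

    def test_mt_abundance_stable_under_subsampling(self):
        # halving both counts binomially moves the ratio by < 3 binomial SEs
        rng = np.random.default_rng(0)
        mt, nuc = 2_000, 100_000
        ratio = mt / nuc
        sub_ratio = rng.binomial(mt, 0.5) / rng.binomial(nuc, 0.5)
        se = ratio * np.sqrt(1 / (mt * 0.5) + 1 / (nuc * 0.5))
        assert abs(sub_ratio - ratio) < 3 * se


def comb_profile(spacing: float, region=(50, 150), amplitude=1000.0, background=100.0) -> SizeProfile:
    """Narrow Gaussians at exact fractional centres on a flat background."""
    grid = np.arange(30, 1001, dtype=float)
    x = np.full(grid.size, background)
    for c in np.arange(region[0], region[1] + 0.01, spacing):
        x += amplitude * np.exp(-0.5 * ((grid - c) / 1.0) ** 2)
    return SizeProfile(counts=np.rint(x).astype(np.int64))


class TestPeriodicity:
    @pytest.mark.parametrize("spacing,tol", [(10.6, 0.1), (10.0, 0.1), (9.0, 0.1), (12.5, 0.1)])
    def test_constructed_comb_recovered(self, spacing, tol):
        res = detect_periodicity(comb_profile(spacing))
        assert res.defined
        assert res.period == pytest.approx(spacing, abs=tol)
        assert res.strength > 0.8

    def test_integer_period_matches_brute_force_integer_lag_search(self):
        # independent oracle: plain argmax over integer lags of the raw
        # (log-free) detrended autocorrelation on an integer-period comb
        prof = comb_profile(11.0)
        res = detect_periodicity(prof)
        lengths = prof.lengths
        mask = (lengths >= 50) & (lengths <= 150)
        x = prof.counts[mask].astype(float)
        best, best_r = None, -np.inf
        for lag in range(8, 15):
            a, b = x[:-lag] - x.mean(), x[lag:] - x.mean()
            r = (a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum())
            if r > best_r:
                best, best_r = lag, r
        assert best == 11
        assert res.period == pytest.approx(11.0, abs=0.1)

    def test_simulated_ladder_period_recovered(self, models):
        lengths = draw_fragment_lengths(models[("graft", "nuclear")], 100_000, np.random.default_rng(1))
        res = detect_periodicity(SizeProfile.from_lengths(lengths))
        assert res.defined
        assert res.period == pytest.approx(10.6, abs=0.3)

    def test_sparse_region_undefined(self):
        res = detect_periodicity(profile_from({60: 5, 70: 5, 80: 5}))
        assert not res.defined and res.period is None


class TestDistributionalRecovery:
    def test_ladder_histogram_modes(self, models):
        rng = np.random.default_rng(1)
        for genome, expected in (("graft", 144), ("host", 169)):
            lengths = draw_fragment_lengths(models[(genome, "nuclear")], 100_000, rng)
            assert abs(modal_length(SizeProfile.from_lengths(lengths)) - expected) <= 1

    def test_gamma_mean_recovery(self, models):
        lengths = draw_fragment_lengths(models[("graft", "mito")], 100_000, np.random.default_rng(3))
        assert mean_length(SizeProfile.from_lengths(lengths)) == pytest.approx(109, abs=1)

    def test_mixing_shorter_component_lowers_mean(self):
        # mean monotonicity on synthetic mixtures
        long_part = np.full(5_000, 170)
        means = [
            mean_length(SizeProfile.from_lengths(np.concatenate([long_part, np.full(k, 110)])))
            for k in (0, 1_000, 2_000, 4_000)
        ]
        assert all(b < a for a, b in zip(means, means[1:]))

    def test_graft_mito_shorter_than_host_mito_across_seeds(self, models):
        # the core biological contrast: tumor-derived mt-cfDNA is shorter
        for seed in range(20):
            rng = np.random.default_rng(seed)
            g = draw_fragment_lengths(models[("graft", "mito")], 10_000, rng)
            h = draw_fragment_lengths(models[("host", "mito")], 10_000, rng)
            assert g.mean() < h.mean()


@given(lengths=st.lists(st.integers(min_value=30, max_value=1000), min_size=1, max_size=200))
def test_profile_conserves_counts_and_mode_attains_max(lengths):
    p = SizeProfile.from_lengths(lengths)
    assert p.n_total == len(lengths)
    mode = modal_length(p)
    counts = pd.Series(lengths).value_counts()
    assert counts[mode] == counts.max()
    assert mode == min(l for l in set(lengths) if counts[l] == counts.max())
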