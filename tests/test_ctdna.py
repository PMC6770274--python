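import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mtfrag.ctdna import (
    VariantSite,
    compute_site_vaf,
    estimate_ctdna_fraction,
    mutation_overlap,
    select_tumor_specific_sites,
    tissue_site_sets,
)
from mtfrag.simulate import SnvSite, demo_snv_sites, simulate_pileup_counts


def site(ref_count, alt_count, **flags):
    defaults = dict(in_primary=True, in_met1=True, in_met2=True, in_cfdna=True, in_normal=False)
    defaults.update(flags)
    return VariantSite("chr1", 100, "T", "C", ref_count=ref_count, alt_count=alt_count, **defaults)


class TestSiteSelection:
    def test_site_present_in_normal_excluded(self):
        assert select_tumor_specific_sites([site(95, 5, in_normal=True)]) == []

    def test_metastasis_only_site_with_support_included(self):
        s = site(95, 5, in_primary=False, in_met1=True, in_met2=False)
        assert select_tumor_specific_sites([s]) == [s]

    def test_depth_and_alt_thresholds(self):
        assert select_tumor_specific_sites([site(7, 1)], min_depth=10, min_alt=2) == []
        assert select_tumor_specific_sites([site(7, 3)], min_depth=10, min_alt=2) == [site(7, 3)]

    def test_simulated_sites_recovered_across_seeds(self):
        # theta=0.1, depth 1000: P(alt < 2) = P(Bin(1000, 0.05) < 2) ~ 0 -> >= 27/28 kept
        spec_sites = demo_snv_sites(n_sites=28, depth=1000)
        for seed in range(20):
            tab = simulate_pileup_counts(spec_sites, 0.1, 0.0, np.random.default_rng(seed))
            sites = [
                VariantSite(r.contig, r.pos, r.ref, r.alt, r.ref_count, r.alt_count,
                            r.in_primary, r.in_met1, r.in_met2, r.in_cfdna, r.in_normal)
                for r in tab.itertuples(index=False)
            ]
            assert len(select_tumor_specific_sites(sites)) >= 27


class TestVaf:
    @pytest.mark.parametrize("ref,alt,expected", [(95, 5, 0.05), (0, 10, 1.0), (9520, 480, 0.048)])
    def test_vaf_arithmetic(self, ref, alt, expected):
        assert compute_site_vaf(site(ref, alt)) == pytest.approx(expected)

    def test_zero_depth_is_error(self):
        with pytest.raises(ValueError):
            compute_site_vaf(site(0, 0))


class TestEstimator:
    def test_mean_vaf_0048_gives_fraction_0096(self):
        sites = [site(9520, 480) for _ in range(28)]
        est = estimate_ctdna_fraction(sites, n_bootstrap=0)
        assert est.ctdna_fraction == pytest.approx(0.096)

    def test_all_zero_vafs_give_zero(self):
        est = estimate_ctdna_fraction([site(100, 0) for _ in range(5)], n_bootstrap=0)
        assert est.ctdna_fraction == 0.0

    def test_unweighted_mean(self):
        sites = [site(90, 10), site(80, 20), site(70, 30)]
        est = estimate_ctdna_fraction(sites, n_bootstrap=0)
        assert est.mean_vaf == pytest.approx(0.20)
        assert est.ctdna_fraction == pytest.approx(0.40)

    def test_fraction_capped_at_one(self):
        est = estimate_ctdna_fraction([site(10, 90)], n_bootstrap=0)
        assert est.ctdna_fraction == 1.0

    def test_empty_site_list_is_error(self):
        with pytest.raises(ValueError):
            estimate_ctdna_fraction([])

    @given(vaf_permille=st.integers(min_value=0, max_value=500), n=st.integers(1, 30))
    def test_homogeneous_vaf_identity(self, vaf_permille, n):
        # identity: every site at VAF v -> estimate exactly min(1, 2v)
        sites = [site(1000 - vaf_permille, vaf_permille) for _ in range(n)]
        est = estimate_ctdna_fraction(sites, n_bootstrap=0)
        assert est.ctdna_fraction == pytest.approx(min(1.0, 2 * vaf_permille / 1000))

    @pytest.mark.parametrize("theta", [0.02, 0.05, 0.1, 0.3])
    def test_estimator_unbiased_over_replicates(self, theta):
        spec_sites = demo_snv_sites(n_sites=28, depth=1000)
        rng = np.random.default_rng(int(theta * 1000))
        estimates = []
        for _ in range(200):
            tab = simulate_pileup_counts(spec_sites, theta, 0.0, rng)
            vafs = tab["alt_count"] / (tab["alt_count"] + tab["ref_count"])
            estimates.append(min(1.0, 2 * vafs.mean()))
        assert np.mean(estimates) == pytest.approx(theta, abs=0.01)

    def test_bootstrap_ci_brackets_estimate_and_covers_truth(self):
        rng = np.random.default_rng(4)
        covered = 0
        for rep in range(200):
            tab = simulate_pileup_counts(demo_snv_sites(28, 1000), 0.1, 0.0, rng)
            sites = [
                VariantSite(r.contig, r.pos, r.ref, r.alt, r.ref_count, r.alt_count,
                            r.in_primary, r.in_met1, r.in_met2, r.in_cfdna, r.in_normal)
                for r in tab.itertuples(index=False)
            ]
            est = estimate_ctdna_fraction(sites, n_bootstrap=500, level=0.95, seed=rep)
            assert est.ci_low <= est.ctdna_fraction <= est.ci_high
            covered += est.ci_low <= 0.1 <= est.ci_high
        assert covered >= 180  # >= 90% empirical coverage at 95% nominal


class TestOverlap:
    def test_identical_and_disjoint_sets(self):
        ov = mutation_overlap({"a": {1, 2}, "b": {1, 2}, "c": {3}})
        assert ov.jaccard[("a", "b")] == 1.0
        assert ov.jaccard[("a", "c")] == 0.0

    def test_partial_overlap(self):
        ov = mutation_overlap({"A": {"a", "b", "c"}, "B": {"b", "c", "d"}})
        assert ov.shared[("A", "B")] == 2
        assert ov.jaccard[("A", "B")] == pytest.approx(0.5)

    def test_single_tissue_rejected(self):
        with pytest.raises(ValueError):
            mutation_overlap({"only": {1}})

    def test_shared_never_exceeds_smaller_set(self):
        sites = [
            site(90, 10),
            VariantSite("chr2", 5, "A", "G", 50, 50, in_primary=False, in_met1=True,
                        in_met2=True, in_cfdna=True, in_normal=False),
        ]
        sets = tissue_site_sets(sites)
        ov = mutation_overlap(sets)
        for (a, b), n in ov.shared.items():
            assert n <= min(ov.set_sizes[a], ov.set_sizes[b])
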