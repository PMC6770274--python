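# Methods

This note documents the generative model behind the synthetic cfDNA
data, the estimators and tests built on top of it, the parameters that
matter, and the numerical choices made where the design was open.

## Generative model

One simulated blood sample mixes fragments from two genomes — the graft
(human tumor) and the host (mouse) — each with a nuclear and a
mitochondrial compartment.

**References.** Toy genomes with uniquely named contigs
(`graft_chr1`/`graft_chrM`, `host_chr1`/`host_chrM`; 2 Mb nuclear
contigs, 16 569 / 16 299 bp mitochondria by default). Sequences are
i.i.d. uniform ACGT, deterministic in (spec, seed). Analyses use
coordinates only; sequence content is plumbing for format realism.

**Fragment counts.** Each of `n_nuclear` nuclear templates is
tumor-derived with probability θ (`tumor_fraction`); mitochondrial
counts are set per genome directly, since mt-cfDNA abundance is governed
by mitochondrial copy number rather than by θ.

**Fragment lengths.** Two parametric families, truncated to
[30, 1000] bp by resampling (very short and very long fragments are
under-represented in real libraries; the window acknowledges that bias
without modelling it):

- *Nucleosomal ladder* (nuclear): with probability `1 − ladder_weight` a
  Gaussian at the modal length (`modal_sd` default 3 bp); with
  probability `ladder_weight` a comb of equally weighted Gaussians at
  `modal − k·period` (k ≥ 1, stopping at `ladder_min` = 50 bp).
  Demo parameters: tumor modal 144 bp with weight 0.3, host modal 169 bp
  with weight 0.1 (the ladder is much weaker in host fragments), period
  10.6 bp — one helical turn, the spacing of nuclease-accessible sites
  on the nucleosome surface.
- *Gamma* (mitochondrial, no nucleosomal structure): given mean and
  shape (default 8, a moderately skewed unimodal shape; only the means
  are constrained by observation). Demo means: tumor 109 bp, host
  143 bp — the core contrast that tumor-derived mt-cfDNA is shorter.

**Placement.** Uniform along contigs (length-weighted across contigs),
except that graft nuclear placement intensity is multiplied by `fold`
inside an optional copy-gain region (demo: fold 2 over
graft_chr1:1,500,000–1,600,000). This is the Poisson-thinning picture of
a duplicated segment in a diploid genome sequenced at uniform depth.

**Variant pileups.** Every configured SNV is tumor-specific and
heterozygous, so its expected cfDNA VAF is θ/2. Alt counts are
`Binomial(depth, θ/2)` plus `Binomial(depth − alt, error_rate)` ref→alt
miscalls (error_rate 0 by default). Tissue presence flags follow the
observed sharing pattern: most sites in both metastases and the primary,
some metastasis-only, a couple primary-only, all in cfDNA, none in the
normal.

**Mapping ambiguity.** A fraction (default 1.5 × 10⁻⁴) of templates
additionally receives a secondary alignment pair on the homologous
contig of the other genome. This stands in for sequence-homology-driven
dual mapping without simulating bases; with a combined two-genome
reference, cross-genome secondary alignments are the operational
signature of reads mappable to both species.

**Determinism.** All randomness flows through `numpy` Generators seeded
from the config seed (separate streams per stage); identical config +
seed reproduces identical SAM/TSV/VCF/JSON bytes. SAM emission writes
one properly-paired primary record pair per fragment, template length
signed with the leftmost mate positive; truth tags `XG` (genome) and
`XC` (compartment) ride in optional fields.

## Analyses

**Fragment extraction.** One fragment per template, counted at the mate
with positive template length; the interval spans the outermost mate
coordinates (0-based half-open internally; SAM/VCF emit 1-based per
their standards). Defaults: proper pairs only, MAPQ ≥ 20, secondary
alignments used solely to mark cross-genome ambiguity. Ambiguous
templates are excluded from per-genome profiles and denominators and
reported separately.

**Size profiles.** Exact integer histograms over [30, 1000] bp; the
mode takes the smallest length on ties; mean mt-cfDNA length is computed
over the same window. Normalized mt abundance divides mitochondrial
fragment count by the same-genome nuclear count, making the two genomes
comparable within one library.

**Ladder periodicity.** The 50–150 bp region of a nuclear histogram is
log-compressed (`log1p`), detrended by subtracting a centered 21 bp
moving average (edge-padded), normalized by its rolling RMS over the
same window, and trimmed by half a window at each edge; the normalized
autocorrelation of the result is evaluated at lags 8–14 bp on a 0.1 bp
grid with linear interpolation, and the maximizing lag (smallest on
ties) is the period. The log compression and local normalization are
what make the detector work when the mono-nucleosome peak falls inside
the analysis region (tumor fragments, modal 144 bp): without them the
peak's detrending residual dominates the autocorrelation and pins the
estimate to the band edge. On noise-free combs the detector is exact to
the grid; on simulated tumor histograms (10⁵ fragments) it returns
10.5 bp for a true 10.6 bp comb, the residual bias coming from integer
binning of fractional tooth positions. Roughly 10⁵ fragments in the
region are needed for ±0.3 bp accuracy; at 2 × 10⁴ the estimate
coarsens to ±0.5 bp. The 21 bp window and 0.1 bp grid are the smallest
that cleanly separate 10.6 from 10.4 bp.

**Species classification.** A template's call is the set of genomes hit
by its passing alignments: both → `ambiguous`, one → that genome,
none → `unmapped`. Fractions are reported on two bases (all templates,
and mapped-only) because survey percentages are quoted on either
convention.

**ctDNA fraction.** Tumor-specific site selection keeps sites present in
≥ 1 tumor lesion, absent in the matched normal, with ≥ `min_alt` (2) alt
reads at depth ≥ `min_depth` (10) in cfDNA — conventional
somatic-support thresholds, configurable. The estimate is
`min(1, 2·f̄)` with f̄ the *unweighted* mean site VAF (matching the
averaging convention of the analysis this emulates; depth-weighting is
deliberately not applied). The site-level bootstrap percentile CI
(default 2000 resamples, 95 %) is an addition, labelled as such in the
output: it captures between-site variability, which dominates
within-site binomial noise at depth ~10⁴.

**Copy-gain test.** 5 kb non-overlapping bins, trailing partial bins
dropped so widths stay constant and counts comparable; each fragment is
assigned to the bin containing its midpoint (counts each template once,
boundary midpoints go to the right bin). The candidate region's bins
are compared against `k` immediately adjacent bins per side (default
`k` = number of region bins) with a one-sided Mann–Whitney test
(region > flank). Exact enumeration of the classical U null when
`n_region·n_flank ≤ 400`, otherwise the normal approximation with tie
and continuity corrections; all-constant input returns p = 1. The two
branches agree within 0.01 for group sizes ≥ 8 per side; at degenerate
sizes (2–3 per group) the normal approximation is intrinsically coarse
and the exact branch always applies.

**Cohort statistics.** Welch's unequal-variance t-test for group
contrasts (the pooled-variance test is unsafe at 46-vs-4 group sizes);
Pearson r with `t = r·√((n−2)/(1−r²))` for burden correlations, missing
covariates dropped pairwise; strict `>` threshold (default 5 %) for
ctDNA dichotomization; longitudinal series require strictly increasing
timepoints and flag any sign reversal among nonzero between-timepoint
changes. No multiple-testing correction by default (nominal p-values
are reported; Benjamini–Hochberg is available via
`mtfrag.cohort.adjust_pvalues`).

## Cohort simulators

Three generators emulate the cohort-level analyses:

- *Group cohort*: per-sample mean mt-cfDNA lengths for cancer
  (mean 109.15 bp, sd 15, n 46), healthy (142.62 bp, sd 10, n 4) and
  autoimmune (140 bp, sd 10, n 20) groups — autoimmune patients resemble
  healthy controls despite elevated total cfDNA.
- *Burden cohort* (n 16): tumor size ~ U(2, 10) (unitless covariate)
  drives mean mt length linearly (intercept 173.25 bp, slope −1.8 bp per
  unit, noise sd 3 bp; population r ≈ −0.81, an effect size that is
  reliably significant at n = 16, as in the cohort this emulates) and
  ctDNA percentage (≈ 1.2·size − 2 plus noise); four samples lack the
  ctDNA-percentage annotation, exercising pairwise-complete handling.
  Tumor size and ctDNA concentration are unitless covariates throughout.
- *Longitudinal series*: four timepoints whose default shape rises then
  falls after the second sample, the reversal pattern of interest.

## What the synthetic data does and does not show

The generator reproduces the *statistical structure* the analyses
assume: binomial graft/host assignment, parametric length mixtures,
uniform placement with a multiplicative gain, heterozygous-site VAFs,
secondary-alignment ambiguity. It does not model sequence content
effects (GC and mappability bias, homology hotspots such as nuclear
mitochondrial insertions), library chemistry (end repair, adapter
artifacts, duplicate structure — the simulator emits deduplicated
fragments), base-level sequencing errors in reads, or biological
heterogeneity (subclonal variants, per-site VAF dispersion,
between-patient fragmentation variability). Passing tests therefore
demonstrate correctness of the estimators and tests under their own
assumptions, and their calibration and power at realistic effect sizes —
not robustness to the biases of real libraries.

## Problem sizes

Default test and demo scales were chosen so each check has the
statistical resolution it needs and no more: 10⁵ fragments for
fragment-size/periodicity recovery (CLT bounds of ±1 bp on means and
modes), 2 × 10⁵ for binomial recovery of θ and the ambiguous fraction,
2 × 10⁴ fragments per null run (×200) for rank-sum calibration — the
null level does not depend on depth — and 10⁵ (×20) for fold-2 power,
28 sites × depth 10⁴ × 20 seeds for estimator recovery with 2000-sample
bootstraps.

## Known limitations

- Species assignment is by contig prefix of a combined reference; no
  alignment-score ambiguity model beyond the configured secondary-pair
  fraction.
- The copy-gain test addresses a single candidate region against local
  flanks; no genome-wide segmentation, GC or mappability correction.
- The periodicity estimate inherits a ~0.1 bp discretization bias from
  integer length binning of fractional comb positions.
- The ctDNA estimator assumes clonal heterozygous sites in a diploid
  genome; copy-number change at a site or subclonality biases 2·f̄.
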