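# Demo configuration: a xenograft-like cfDNA sample.
# All keys are optional; omitted ones take the package defaults.
seed: 1
outdir: mtfrag_out

simulate:
  n_nuclear: 200000          # nuclear templates (graft share = tumor_fraction)
  n_mito_graft: 20000        # tumor-derived mitochondrial fragments
  n_mito_host: 10000
  tumor_fraction: 0.096      # ctDNA fraction theta; per-site expected VAF = theta/2
  ambiguous_fraction: 1.5e-4 # templates that also align on the other genome
  n_snv_sites: 28            # tumor-specific heterozygous SNVs
  snv_depth: 10000
  error_rate: 0.0
  cnv:
    contig: graft_chr1
    start: 1500000
    end: 1600000
    fold: 2.0                # copy-gain intensity multiplier

ctdna:
  min_depth: 10
  min_alt: 2
  n_bootstrap: 2000
  ci_level: 0.95

cnv:
  bin_width: 5000
  flank_bins_per_side: null  # default: one flank bin per region bin, each side

cohort:
  ctdna_threshold_percent: 5.0
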