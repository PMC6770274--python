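"""Synthetic xenograft cfDNA generator.

Emits, with known ground truth, everything the downstream analyses
consume: paired-end alignment records on a combined graft+host
reference, per-site variant pileup counts with tissue presence flags, a
truth VCF, and cohort tables.  The generative model:

* each of ``n_nuclear`` nuclear fragments is tumor-derived (graft) with
  probability ``tumor_fraction`` (the ctDNA fraction θ), host otherwise;
* mitochondrial fragment counts are set per genome directly;
* fragment lengths come from per-(genome, compartment) models
  (:mod:`mtfrag.sizemodels`);
* placement is uniform along contigs, except that graft nuclear
  placement intensity is multiplied by ``fold`` inside an optional
  copy-gain region;
* every tumor-specific SNV is heterozygous in a diploid tumor genome, so
  its expected cfDNA variant allele frequency is θ/2; alt counts are
  Binomial(depth, θ/2) plus ref→alt miscalls at ``error_rate``;
* a small ``ambiguous_fraction`` of fragments additionally receives a
  secondary alignment on the homologous contig of the other genome,
  standing in for reads that map to both references.

Identical config + seed reproduce identical output bytes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .errors import ConfigError
from .genomes import GRAFT, HOST, MITO, NUCLEAR, ContigIndex, GenomeSpec, default_genome_pair
from .sizemodels import GAMMA, LADDER, FragmentLengthModel, draw_fragment_lengths

#: canonical in-memory fragment table columns
FRAGMENT_COLUMNS = ["read_id", "genome", "compartment", "contig", "start", "end", "length", "ambiguous"]

TUMOR_TISSUES = ("primary", "met1", "met2")


@dataclass(frozen=True)
class SnvSite:
    """A tumor-specific SNV with its simulated sequencing depth in cfDNA."""

    contig: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    depth: int
    in_primary: bool = True
    in_met1: bool = True
    in_met2: bool = True
    in_normal: bool = False


@dataclass(frozen=True)
class CnvRegion:
    contig: str
    start: int  # 0-based half-open
    end: int
    fold: float

    def __post_init__(self):
        if self.fold < 1.0:
            raise ConfigError(f"cnv fold must be >= 1, got {self.fold}")
        if not 0 <= self.start < self.end:
            raise ConfigError(f"bad cnv region [{self.start}, {self.end})")


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulated cfDNA sample."""

    seed: int = 1
    n_nuclear: int = 200_000
    n_mito_graft: int = 20_000
    n_mito_host: int = 10_000
    tumor_fraction: float = 0.096
    models: dict[tuple[str, str], FragmentLengthModel] = field(default_factory=dict)
    ambiguous_fraction: float = 1.5e-4
    snv_sites: tuple[SnvSite, ...] = ()
    error_rate: float = 0.0
    cnv_region: CnvRegion | None = None

    def __post_init__(self):
        for name, val in (
            ("tumor_fraction", self.tumor_fraction),
            ("ambiguous_fraction", self.ambiguous_fraction),
            ("error_rate", self.error_rate),
        ):
            if not 0.0 <= val <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {val}")
        for name in ("n_nuclear", "n_mito_graft", "n_mito_host"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        object.__setattr__(self, "snv_sites", tuple(self.snv_sites))


def demo_models() -> dict[tuple[str, str], FragmentLengthModel]:
    """The demo fragment-length models.

    Tumor nuclear fragments peak at 144 bp with a pronounced 10.6 bp
    sub-nucleosomal ladder; host nuclear fragments peak at 169 bp with a
    much weaker ladder.  Mitochondrial lengths are gamma with means 109
    (tumor) and 143 bp (host).
    """
    return {
        (GRAFT, NUCLEAR): FragmentLengthModel(
            kind=LADDER, modal_length=144, modal_sd=3.0, ladder_period=10.6, ladder_min=50, ladder_weight=0.3
        ),
        (HOST, NUCLEAR): FragmentLengthModel(
            kind=LADDER, modal_length=169, modal_sd=3.0, ladder_period=10.6, ladder_min=50, ladder_weight=0.1
        ),
        (GRAFT, MITO): FragmentLengthModel(kind=GAMMA, mean_length=109, shape=8),
        (HOST, MITO): FragmentLengthModel(kind=GAMMA, mean_length=143, shape=8),
    }


def demo_snv_sites(n_sites: int = 28, depth: int = 10_000, contig: str = "graft_chr1") -> tuple[SnvSite, ...]:
    """Evenly spaced heterozygous tumor-specific sites on a graft contig.

    Tissue flags mimic the observed sharing pattern: most sites in both
    bone metastases and the primary, a few metastasis-only, a couple
    primary-only; all detected in cfDNA, none in the normal.
    """
    sites = []
    for i in range(n_sites):
        pos = 10_000 + i * 50_000 + 1
        if i % 7 == 5:
            flags = dict(in_primary=False, in_met1=True, in_met2=True)
        elif i % 7 == 6:
            flags = dict(in_primary=True, in_met1=False, in_met2=False)
        else:
            flags = dict(in_primary=True, in_met1=True, in_met2=True)
        sites.append(SnvSite(contig=contig, pos=pos, ref="T", alt="C", depth=depth, **flags))
    return tuple(sites)


def demo_config(seed: int = 1, **overrides) -> SimulationConfig:
    """Demo configuration mirroring the study's regime.

    θ = 0.096 (so expected per-site VAF 4.8%), 28 heterozygous sites at
    depth 10 000, a fold-2 copy gain over 100 kb of the graft nuclear
    contig, ambiguous fraction 1.5e-4.
    """
    defaults = dict(
        seed=seed,
        n_nuclear=200_000,
        n_mito_graft=20_000,
        n_mito_host=10_000,
        tumor_fraction=0.096,
        models=demo_models(),
        ambiguous_fraction=1.5e-4,
        snv_sites=demo_snv_sites(),
        error_rate=0.0,
        cnv_region=CnvRegion(contig="graft_chr1", start=1_500_000, end=1_600_000, fold=2.0),
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


# ---------------------------------------------------------------------------
# fragment simulation


def _place_uniform(n: int, contig_lengths: np.ndarray, frag_lengths: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    """Choose a contig (length-weighted) and a uniform start for each fragment."""
    probs = contig_lengths / contig_lengths.sum()
    which = rng.choice(contig_lengths.size, size=n, p=probs)
    span = np.maximum(contig_lengths[which] - frag_lengths, 1)
    starts = np.floor(rng.random(n) * span).astype(np.int64)
    return which, starts


def _place_with_cnv(
    n: int,
    contig_names: list[str],
    contig_lengths: np.ndarray,
    frag_lengths: np.ndarray,
    cnv: CnvRegion,
    rng,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform placement with intensity multiplied by ``fold`` in the gain region."""
    region_len = cnv.end - cnv.start
    eff = contig_lengths.astype(float).copy()
    ci = contig_names.index(cnv.contig)
    eff[ci] += (cnv.fold - 1.0) * region_len
    which = rng.choice(len(contig_names), size=n, p=eff / eff.sum())
    starts = np.empty(n, dtype=np.int64)
    on_cnv_contig = which == ci
    # non-CNV contigs: plain uniform
    for j in np.unique(which[~on_cnv_contig]):
        m = which == j
        span = np.maximum(contig_lengths[j] - frag_lengths[m], 1)
        starts[m] = np.floor(rng.random(m.sum()) * span).astype(np.int64)
    m = on_cnv_contig
    k = int(m.sum())
    if k:
        p_region = cnv.fold * region_len / eff[ci]
        in_region = rng.random(k) < p_region
        s = np.empty(k, dtype=np.int64)
        lr = frag_lengths[m]
        span_r = np.maximum(region_len - lr, 1)
        s[in_region] = cnv.start + np.floor(rng.random(int(in_region.sum())) * span_r[in_region]).astype(np.int64)
        # complement: uniform over [0, start) ∪ [end, L)
        out = ~in_region
        comp_len = contig_lengths[ci] - region_len
        u = np.floor(rng.random(int(out.sum())) * np.maximum(comp_len - lr[out], 1)).astype(np.int64)
        u = np.where(u >= cnv.start, u + region_len, u)
        s[out] = u
        starts[m] = s
    return which, starts


def simulate_fragments(
    config: SimulationConfig, index: ContigIndex, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, dict]:
    """Simulate the fragment table for one sample.

    Returns ``(fragments, truth)`` where ``fragments`` has the columns
    in :data:`FRAGMENT_COLUMNS` and ``truth`` records θ, the expected
    per-site VAF (θ/2), the copy-gain region and per-class counts.
    """
    if rng is None:
        rng = np.random.default_rng([int(config.seed), 0])
    models = config.models or demo_models()

    n = config.n_nuclear
    graft_mask = rng.random(n) < config.tumor_fraction
    n_g, n_h = int(graft_mask.sum()), int(n - graft_mask.sum())

    blocks = []
    for genome, compartment, count in (
        (GRAFT, NUCLEAR, n_g),
        (HOST, NUCLEAR, n_h),
        (GRAFT, MITO, config.n_mito_graft),
        (HOST, MITO, config.n_mito_host),
    ):
        names = index.contigs(genome=genome, compartment=compartment)
        if count and not names:
            raise ConfigError(f"no {genome} {compartment} contig in index")
        if not count:
            continue
        lengths = draw_fragment_lengths(models[(genome, compartment)], count, rng)
        contig_lengths = np.array([index.length_of(c) for c in names])
        cnv = config.cnv_region
        if genome == GRAFT and compartment == NUCLEAR and cnv is not None and cnv.contig in names:
            which, starts = _place_with_cnv(count, names, contig_lengths, lengths, cnv, rng)
        else:
            which, starts = _place_uniform(count, contig_lengths, lengths, rng)
        ends = np.minimum(starts + lengths, contig_lengths[which])
        blocks.append(
            pd.DataFrame(
                {
                    "genome": genome,
                    "compartment": compartment,
                    "contig": pd.Categorical.from_codes(which, categories=names).astype(str),
                    "start": starts,
                    "end": ends,
                    "length": ends - starts,
                }
            )
        )
    frags = pd.concat(blocks, ignore_index=True) if blocks else pd.DataFrame(
        columns=[c for c in FRAGMENT_COLUMNS if c not in ("read_id", "ambiguous")]
    )
    total = len(frags)
    frags.insert(0, "read_id", [f"frag{i:08d}" for i in range(total)])
    frags["ambiguous"] = rng.random(total) < config.ambiguous_fraction
    frags = frags[FRAGMENT_COLUMNS]

    truth = {
        "seed": int(config.seed),
        "tumor_fraction": float(config.tumor_fraction),
        "expected_site_vaf": float(config.tumor_fraction) / 2.0,
        "n_fragments": total,
        "n_nuclear_graft": n_g,
        "n_nuclear_host": n_h,
        "n_mito_graft": int(config.n_mito_graft),
        "n_mito_host": int(config.n_mito_host),
        "n_ambiguous": int(frags["ambiguous"].sum()),
        "cnv_region": None if config.cnv_region is None else asdict(config.cnv_region),
        "models": {f"{g}:{c}": asdict(m) for (g, c), m in models.items()},
    }
    return frags, truth


# ---------------------------------------------------------------------------
# SAM emission

_READ_LEN = 50


def _sam_header(index: ContigIndex) -> pysam.AlignmentHeader:
    sq = [{"SN": name, "LN": index.length_of(name)} for name in index.entries]
    return pysam.AlignmentHeader.from_dict({"HD": {"VN": "1.6", "SO": "unsorted"}, "SQ": sq})


def emit_alignments(fragments: pd.DataFrame, index: ContigIndex, path: str | Path) -> Path:
    """Write one properly-paired primary record pair per fragment (SAM).

    The leftmost mate carries a positive template length equal to the
    fragment length; ambiguous fragments get an extra secondary pair on
    the homologous contig of the other genome.  Truth tags: ``XG``
    (genome), ``XC`` (compartment).
    """
    path = Path(path)
    header = _sam_header(index)
    tid = {name: i for i, name in enumerate(index.entries)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for row in fragments.itertuples(index=False):
            contig_len = index.length_of(row.contig)
            if row.start < 0 or row.end > contig_len or row.start >= row.end:
                raise ValueError(
                    f"fragment {row.read_id} interval [{row.start}, {row.end}) outside contig {row.contig}"
                )
            _write_pair(out, header, tid, row, row.contig, secondary=False)
            if row.ambiguous:
                other = index.homolog.get(row.contig)
                if other is not None:
                    _write_pair(out, header, tid, row, other, secondary=True)
    return path


def _write_pair(out, header, tid, row, contig, secondary: bool):
    length = int(row.end - row.start)
    rlen = min(_READ_LEN, length)
    start = int(row.start)
    contig_len = out.header.get_reference_length(contig)
    if secondary:  # clamp homolog placement to the other contig
        start = min(start, max(contig_len - length, 0))
    end = min(start + length, contig_len)
    r2_start = max(end - rlen, start)
    sec_flag = 0x100 if secondary else 0
    for is_read1 in (True, False):
        a = pysam.AlignedSegment(header)
        a.query_name = row.read_id
        a.reference_id = tid[contig]
        a.mapping_quality = 60
        a.cigarstring = f"{rlen}M"
        a.flag = (0x1 | 0x2 | (0x20 | 0x40 if is_read1 else 0x10 | 0x80)) | sec_flag
        a.reference_start = start if is_read1 else r2_start
        a.next_reference_id = tid[contig]
        a.next_reference_start = r2_start if is_read1 else start
        a.template_length = length if is_read1 else -length
        a.set_tag("XG", row.genome)
        a.set_tag("XC", row.compartment)
        out.write(a)


# ---------------------------------------------------------------------------
# variant pileups

PILEUP_COLUMNS = [
    "contig", "pos", "ref", "alt", "ref_count", "alt_count",
    "in_primary", "in_met1", "in_met2", "in_cfdna", "in_normal", "zero_depth",
]


def simulate_pileup_counts(
    sites: tuple[SnvSite, ...], tumor_fraction: float, error_rate: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw cfDNA ref/alt counts for each site under the heterozygous model."""
    rows = []
    vaf = tumor_fraction / 2.0
    for s in sites:
        if s.depth <= 0:
            rows.append((s.contig, s.pos, s.ref, s.alt, 0, 0, s.in_primary, s.in_met1, s.in_met2, False, s.in_normal, True))
            continue
        alt_true = int(rng.binomial(s.depth, vaf))
        alt = alt_true + int(rng.binomial(s.depth - alt_true, error_rate)) if error_rate > 0 else alt_true
        rows.append(
            (s.contig, s.pos, s.ref, s.alt, s.depth - alt, alt,
             s.in_primary, s.in_met1, s.in_met2, alt > 0, s.in_normal, False)
        )
    return pd.DataFrame(rows, columns=PILEUP_COLUMNS)


def emit_variant_pileups(
    config: SimulationConfig,
    index: ContigIndex,
    tsv_path: str | Path,
    vcf_path: str | Path,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Write the pileup TSV and the truth VCF of configured sites."""
    if not config.snv_sites:
        raise ConfigError("emit_variant_pileups requires at least one snv_site")
    if rng is None:
        rng = np.random.default_rng([int(config.seed), 1])
    table = simulate_pileup_counts(config.snv_sites, config.tumor_fraction, config.error_rate, rng)
    table.to_csv(tsv_path, sep="\t", index=False)
    _write_truth_vcf(config, index, vcf_path)
    return table


def _write_truth_vcf(config: SimulationConfig, index: ContigIndex, vcf_path: str | Path) -> None:
    header = pysam.VariantHeader()
    for name in index.entries:
        header.contigs.add(name, length=index.length_of(name))
    header.info.add("TISSUES", ".", "String", "Tumor tissues carrying the variant")
    header.info.add("EVAF", 1, "Float", "Expected cfDNA VAF under heterozygous model (theta/2)")
    with pysam.VariantFile(str(vcf_path), "w", header=header) as vcf:
        for s in config.snv_sites:
            rec = vcf.new_record(contig=s.contig, start=s.pos - 1, stop=s.pos, alleles=(s.ref, s.alt))
            tissues = [t for t, f in zip(TUMOR_TISSUES, (s.in_primary, s.in_met1, s.in_met2)) if f]
            rec.info["TISSUES"] = ",".join(tissues) if tissues else "."
            rec.info["EVAF"] = config.tumor_fraction / 2.0
            vcf.write(rec)


# ---------------------------------------------------------------------------
# cohort tables

COHORT_COLUMNS = [
    "sample_id", "patient_id", "group", "timepoint", "mean_mt_length",
    "ctdna_percent", "tumor_size", "ctdna_concentration", "disease_state",
]


def simulate_group_cohort(
    seed: int,
    n_cancer: int = 46,
    n_healthy: int = 4,
    n_autoimmune: int = 20,
    cancer_mean: float = 109.15,
    cancer_sd: float = 15.0,
    healthy_mean: float = 142.62,
    healthy_sd: float = 10.0,
    autoimmune_mean: float = 140.0,
    autoimmune_sd: float = 10.0,
) -> pd.DataFrame:
    """Per-sample mean mt-cfDNA lengths for a three-group cohort.

    Defaults follow the reanalyzed plasma cohort: cancer patients with
    markedly shorter mt-cfDNA (mean 109.15 bp, n=46) than healthy
    controls (142.62 bp, n=4), with autoimmune patients resembling the
    healthy group despite elevated total cfDNA.
    """
    rng = np.random.default_rng([int(seed), 10])
    rows = []
    for group, n, mu, sd in (
        ("cancer", n_cancer, cancer_mean, cancer_sd),
        ("healthy", n_healthy, healthy_mean, healthy_sd),
        ("autoimmune", n_autoimmune, autoimmune_mean, autoimmune_sd),
    ):
        vals = rng.normal(mu, sd, size=n)
        for i, v in enumerate(vals):
            rows.append((f"{group}_{i:03d}", f"{group}_{i:03d}", group, 0, float(max(v, 40.0)),
                         np.nan, np.nan, np.nan, group))
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def simulate_burden_cohort(
    seed: int,
    n: int = 16,
    intercept: float = 173.25,
    slope: float = -1.8,
    noise_sd: float = 3.0,
    n_missing_ctdna: int = 4,
) -> pd.DataFrame:
    """Cohort in which mean mt-cfDNA length decreases with tumor burden.

    Emulates the liver-cancer reanalysis: tumor size (unitless covariate)
    drives both ctDNA percentage and a linear decrease in mt-cfDNA
    length; a few samples lack the ctDNA-percentage annotation.
    """
    rng = np.random.default_rng([int(seed), 11])
    size = rng.uniform(2.0, 10.0, size=n)
    mt = intercept + slope * size + rng.normal(0.0, noise_sd, size=n)
    ctdna_pct = np.clip(1.2 * size - 2.0 + rng.normal(0.0, 1.5, size=n), 0.0, 60.0)
    conc = ctdna_pct * rng.uniform(0.8, 1.2, size=n)
    missing = rng.choice(n, size=min(n_missing_ctdna, n), replace=False)
    ctdna_pct[missing] = np.nan
    rows = []
    for i in range(n):
        rows.append((f"hcc_{i:03d}", f"hcc_{i:03d}", "cancer", 0, float(mt[i]),
                     float(ctdna_pct[i]), float(size[i]), float(conc[i]), "cancer"))
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def simulate_longitudinal_series(
    seed: int,
    patient_id: str = "patient_05",
    mt_lengths: tuple[float, ...] = (150.0, 160.0, 140.0, 130.0),
    states: tuple[str, ...] = ("progressing", "stable", "progressing", "progressing"),
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """One patient's mean mt-cfDNA length across ordered timepoints.

    The default shape rises then falls after the second timepoint, the
    pattern observed over four 3-month-interval samples in the
    longitudinal prostate-cancer case.
    """
    rng = np.random.default_rng([int(seed), 12])
    rows = []
    for t, (mt, st) in enumerate(zip(mt_lengths, states)):
        v = mt + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        rows.append((f"{patient_id}_t{t}", patient_id, "cancer", t, float(v), np.nan, np.nan, np.nan, st))
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_truth_json(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
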