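"""Pipeline orchestration: simulate → classify → profile → ctdna → cnv → cohort.

A single YAML config (validated against a nested schema of defaults)
drives all stages; the seed is propagated to every stochastic stage, so
rerunning an unchanged config reproduces all output bytes.  Each stage
records its key metrics into a consolidated run report.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import classify as classify_mod
from . import cnv as cnv_mod
from . import cohort as cohort_mod
from . import ctdna as ctdna_mod
from . import profiling
from . import simulate as sim
from .errors import ConfigError, StageError
from .fragments import extract_fragments, index_from_alignments, write_fragment_table
from .genomes import GRAFT, HOST, MITO, NUCLEAR, build_contig_index, build_toy_genomes, default_genome_pair

log = logging.getLogger("mtfrag")

STAGES = ("simulate", "classify", "profile", "ctdna", "cnv", "cohort")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "outdir": "mtfrag_out",
    "log_level": "INFO",
    "stages": {s: True for s in STAGES},
    "simulate": {
        "n_nuclear": 200_000,
        "n_mito_graft": 20_000,
        "n_mito_host": 10_000,
        "tumor_fraction": 0.096,
        "ambiguous_fraction": 1.5e-4,
        "error_rate": 0.0,
        "n_snv_sites": 28,
        "snv_depth": 10_000,
        "nuclear_length": 2_000_000,
        "host_mito_length": 16_299,
        "write_fasta": False,
        "cnv": {"contig": "graft_chr1", "start": 1_500_000, "end": 1_600_000, "fold": 2.0},
    },
    "classify": {"min_mapq": 0, "bam": None},
    "profile": {
        "min_mapq": 20,
        "bam": None,
        "periodicity_region": [50, 150],
        "periodicity_band": [8.0, 14.0],
    },
    "ctdna": {
        "pileup": None,
        "min_depth": 10,
        "min_alt": 2,
        "n_bootstrap": 2000,
        "ci_level": 0.95,
    },
    "cnv": {"bin_width": 5000, "flank_bins_per_side": None, "fragments": None},
    "cohort": {"table": None, "ctdna_threshold_percent": 5.0},
}


# ---------------------------------------------------------------------------
# config handling


def _merge(defaults: dict, given: dict, path: str, errors: list[str]) -> dict:
    out = copy.deepcopy(defaults)
    for key, val in (given or {}).items():
        if key not in defaults:
            errors.append(f"unknown key {path + key!r}")
            continue
        if isinstance(defaults[key], dict) and defaults[key] and not key == "stages":
            if val is None:
                continue
            if not isinstance(val, dict):
                errors.append(f"{path + key!r} must be a mapping")
                continue
            out[key] = _merge(defaults[key], val, path + key + ".", errors)
        elif key == "stages":
            if not isinstance(val, dict):
                errors.append("'stages' must be a mapping of stage name to bool")
                continue
            for s, flag in val.items():
                if s not in STAGES:
                    errors.append(f"unknown stage {s!r}")
                else:
                    out["stages"][s] = bool(flag)
        else:
            out[key] = val
    return out


def _range_checks(cfg: dict, errors: list[str]) -> None:
    s = cfg["simulate"]
    for name in ("tumor_fraction", "ambiguous_fraction", "error_rate"):
        v = s[name]
        if not (isinstance(v, (int, float)) and 0.0 <= v <= 1.0):
            errors.append(f"simulate.{name} must be in [0, 1], got {v!r}")
    for name in ("n_nuclear", "n_mito_graft", "n_mito_host", "n_snv_sites", "snv_depth"):
        if not (isinstance(s[name], int) and s[name] >= 0):
            errors.append(f"simulate.{name} must be a non-negative integer")
    cnv = s["cnv"]
    if cnv is not None and cnv.get("fold", 1.0) < 1.0:
        errors.append("simulate.cnv.fold must be >= 1")
    if cfg["cnv"]["bin_width"] <= 0:
        errors.append("cnv.bin_width must be > 0")
    level = cfg["ctdna"]["ci_level"]
    if not 0.0 < level < 1.0:
        errors.append("ctdna.ci_level must be in (0, 1)")


def validate_config(source: str | Path | dict | None) -> dict:
    """Normalize a YAML file or dict against the defaults.

    Unknown keys are rejected; violations are aggregated into one
    :class:`ConfigError`.  An empty source yields the full defaults.
    """
    if source is None:
        given: dict = {}
    elif isinstance(source, dict):
        given = source
    else:
        with open(source) as fh:
            given = yaml.safe_load(fh) or {}
        if not isinstance(given, dict):
            raise ConfigError(f"config file {source} must contain a mapping")
    errors: list[str] = []
    cfg = _merge(DEFAULT_CONFIG, given, "", errors)
    _range_checks(cfg, errors)
    if errors:
        raise ConfigError("; ".join(errors), errors=errors)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _dump_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# stages


def _simulation_config(cfg: dict) -> sim.SimulationConfig:
    s = cfg["simulate"]
    cnv = s["cnv"]
    return sim.SimulationConfig(
        seed=cfg["seed"],
        n_nuclear=s["n_nuclear"],
        n_mito_graft=s["n_mito_graft"],
        n_mito_host=s["n_mito_host"],
        tumor_fraction=s["tumor_fraction"],
        models=sim.demo_models(),
        ambiguous_fraction=s["ambiguous_fraction"],
        snv_sites=sim.demo_snv_sites(n_sites=s["n_snv_sites"], depth=s["snv_depth"]),
        error_rate=s["error_rate"],
        cnv_region=None
        if cnv is None
        else sim.CnvRegion(contig=cnv["contig"], start=cnv["start"], end=cnv["end"], fold=cnv["fold"]),
    )


def run_pipeline(config: str | Path | dict | None, outdir: str | Path | None = None) -> dict:
    """Run the enabled stages in dependency order; return the run report.

    A stage failure halts its dependents but the report still carries
    the completed stages' metrics.  Artifacts land under ``outdir``.
    """
    cfg = validate_config(config)
    out = Path(outdir if outdir is not None else cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg["seed"], "config_hash": config_hash(cfg), "stages": {}}
    enabled = cfg["stages"]
    artifacts: dict = {}

    order = [
        ("simulate", _stage_simulate, ()),
        ("classify", _stage_classify, ("simulate",)),
        ("profile", _stage_profile, ("simulate",)),
        ("ctdna", _stage_ctdna, ("simulate",)),
        ("cnv", _stage_cnv, ("profile",)),
        ("cohort", _stage_cohort, ()),
    ]
    failed: set[str] = set()
    for name, fn, deps in order:
        if not enabled.get(name, False):
            report["stages"][name] = {"status": "skipped"}
            continue
        # external inputs in the config satisfy a missing dependency stage
        dep_failed = any(d in failed for d in deps)
        if dep_failed:
            report["stages"][name] = {"status": "halted", "reason": "dependency failed"}
            continue
        t0 = time.monotonic()
        try:
            metrics = fn(cfg, out, artifacts)
        except Exception as exc:  # noqa: BLE001 — report and halt dependents
            log.error("stage %s failed: %s", name, exc)
            failed.add(name)
            report["stages"][name] = {"status": "failed", "error": str(exc)}
            continue
        log.info("stage %s done in %.2fs", name, time.monotonic() - t0)
        report["stages"][name] = {"status": "ok", "metrics": metrics}
    _dump_json(report, out / "report.json")
    return report


def _stage_simulate(cfg: dict, out: Path, artifacts: dict) -> dict:
    sc = _simulation_config(cfg)
    s = cfg["simulate"]
    graft, host = default_genome_pair(
        nuclear_length=s["nuclear_length"], host_mito_length=s["host_mito_length"]
    )
    if s["write_fasta"]:
        _, index = build_toy_genomes(graft, host, cfg["seed"], out / "genomes")
    else:
        index = build_contig_index(graft, host)
    frags, truth = sim.simulate_fragments(sc, index)
    sam_path = out / "simulated.sam"
    sim.emit_alignments(frags, index, sam_path)
    write_fragment_table(frags, out / "truth_fragments.tsv")
    sim.write_truth_json(truth, out / "truth.json")
    pileup_path = out / "pileup.tsv"
    vcf_path = out / "truth_sites.vcf"
    if sc.snv_sites:
        sim.emit_variant_pileups(sc, index, pileup_path, vcf_path)
    artifacts.update(index=index, sam=sam_path, pileup=pileup_path, truth=truth, truth_fragments=frags)
    return {
        "n_fragments": truth["n_fragments"],
        "tumor_fraction": truth["tumor_fraction"],
        "n_ambiguous": truth["n_ambiguous"],
    }


def _input_sam(cfg: dict, stage: str, artifacts: dict):
    path = cfg[stage]["bam"]
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise StageError(stage, f"input alignments not found: {path}")
        return path, index_from_alignments(path)
    if "sam" not in artifacts:
        raise StageError(stage, "no input alignments: enable the simulate stage or set a bam path")
    return artifacts["sam"], artifacts["index"]


def _stage_classify(cfg: dict, out: Path, artifacts: dict) -> dict:
    sam, index = _input_sam(cfg, "classify", artifacts)
    calls = classify_mod.classify_alignments(sam, index, min_mapq=cfg["classify"]["min_mapq"])
    summary = classify_mod.summarize_classification(calls)
    _dump_json(summary.as_dict(), out / "classification.json")
    return summary.as_dict()


def _stage_profile(cfg: dict, out: Path, artifacts: dict) -> dict:
    sam, index = _input_sam(cfg, "profile", artifacts)
    frags, skipped = extract_fragments(sam, index, min_mapq=cfg["profile"]["min_mapq"])
    artifacts["fragments"] = frags
    metrics: dict = {"n_fragments": int(len(frags)), "skipped": skipped, "profiles": {}}
    region = tuple(cfg["profile"]["periodicity_region"])
    band = tuple(cfg["profile"]["periodicity_band"])
    nuclear_counts: dict[str, int] = {}
    for genome in (GRAFT, HOST):
        for compartment in (NUCLEAR, MITO):
            prof = profiling.size_histogram(frags, genome=genome, compartment=compartment)
            key = f"{genome}_{compartment}"
            profiling.profile_table(prof).to_csv(out / f"profile_{key}.tsv", sep="\t", index=False)
            entry = {"n": prof.n_total, "mode": prof.mode, "mean": prof.mean}
            if compartment == NUCLEAR:
                nuclear_counts[genome] = prof.n_total
                per = profiling.detect_periodicity(prof, region=region, band=band)
                entry["periodicity_bp"] = per.period
                entry["periodicity_strength"] = per.strength
            metrics["profiles"][key] = entry
    for genome in (GRAFT, HOST):
        mt_n = metrics["profiles"][f"{genome}_{MITO}"]["n"]
        nuc_n = nuclear_counts[genome]
        metrics["profiles"][f"{genome}_{MITO}"]["normalized_mt_abundance"] = (
            profiling.normalized_mt_abundance(mt_n, nuc_n) if nuc_n else None
        )
    _dump_json(metrics, out / "profiles.json")
    return metrics


def _stage_ctdna(cfg: dict, out: Path, artifacts: dict) -> dict:
    path = cfg["ctdna"]["pileup"] or artifacts.get("pileup")
    if path is None or not Path(path).exists():
        raise StageError("ctdna", "no pileup table: enable simulate or set ctdna.pileup")
    c = cfg["ctdna"]
    sites = ctdna_mod.read_pileup_tsv(path)
    selected = ctdna_mod.select_tumor_specific_sites(sites, min_depth=c["min_depth"], min_alt=c["min_alt"])
    est = ctdna_mod.estimate_ctdna_fraction(
        selected, n_bootstrap=c["n_bootstrap"], level=c["ci_level"], seed=cfg["seed"]
    )
    overlap = ctdna_mod.mutation_overlap(ctdna_mod.tissue_site_sets(sites))
    overlap.as_frame().to_csv(out / "mutation_overlap.tsv", sep="\t", index=False)
    _dump_json(est.as_dict(), out / "ctdna_estimate.json")
    return est.as_dict()


def _stage_cnv(cfg: dict, out: Path, artifacts: dict) -> dict:
    frags = artifacts.get("fragments")
    if frags is None:
        frag_path = cfg["cnv"]["fragments"]
        if frag_path is None:
            raise StageError("cnv", "no fragments: enable the profile stage or set cnv.fragments")
        frags = pd.read_csv(frag_path, sep="\t")
    region_cfg = cfg["simulate"]["cnv"]
    if region_cfg is None:
        raise StageError("cnv", "no candidate region configured")
    index = artifacts.get("index")
    contig = region_cfg["contig"]
    nuclear = frags[(frags["compartment"] == NUCLEAR) & (frags["contig"] == contig)]
    length = index.length_of(contig) if index is not None else int(nuclear["end"].max())
    bins = cnv_mod.tile_genome({contig: length}, width=cfg["cnv"]["bin_width"])
    bins = cnv_mod.count_fragments(nuclear, bins)
    cnv_mod.write_bins(bins, out / "bins.tsv")
    test = cnv_mod.mann_whitney_gain(
        bins,
        (contig, region_cfg["start"], region_cfg["end"]),
        flank_bins_per_side=cfg["cnv"]["flank_bins_per_side"],
    )
    _dump_json(test.as_dict(), out / "cnv_test.json")
    return test.as_dict()


def _stage_cohort(cfg: dict, out: Path, artifacts: dict) -> dict:
    table_path = cfg["cohort"]["table"]
    if table_path is not None:
        table = cohort_mod.read_cohort_table(table_path)
        burden = table
    else:
        table = sim.simulate_group_cohort(cfg["seed"])
        burden = sim.simulate_burden_cohort(cfg["seed"])
        table.to_csv(out / "cohort_groups.tsv", sep="\t", index=False)
        burden.to_csv(out / "cohort_burden.tsv", sep="\t", index=False)
    metrics: dict = {}
    groups = cohort_mod.group_series(table)
    if "cancer" in groups and "healthy" in groups and len(groups["cancer"]) > 1 and len(groups["healthy"]) > 1:
        metrics["cancer_vs_healthy"] = cohort_mod.welch_t_test(groups["cancer"], groups["healthy"]).as_dict()
    pairs = [("mean_mt_length", "tumor_size"), ("mean_mt_length", "ctdna_concentration"),
             ("mean_mt_length", "ctdna_percent")]
    correlations = {}
    for x, y in pairs:
        if x in burden.columns and y in burden.columns:
            try:
                correlations[f"{x}:{y}"] = cohort_mod.pearson_correlation(
                    burden[x], burden[y], variable_x=x, variable_y=y
                ).as_dict()
            except ValueError:
                continue
    if correlations:
        metrics["correlations"] = correlations
    high, low, cmp = cohort_mod.dichotomize_by_ctdna(
        burden, threshold=cfg["cohort"]["ctdna_threshold_percent"]
    )
    metrics["ctdna_dichotomy"] = {
        "n_high": int(len(high)),
        "n_low": int(len(low)),
        "comparison": None if cmp is None else cmp.as_dict(),
    }
    _dump_json(metrics, out / "cohort_stats.json")
    return metrics
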