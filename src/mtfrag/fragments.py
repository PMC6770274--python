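"""Fragment extraction from paired-end alignments.

A sequenced cfDNA molecule appears as a properly-paired read pair; the
fragment length is the outer mate span (the SAM template length), and
each template is counted once, at its leftmost mate.  Genome and
compartment are assigned from the contig index; templates that also
carry a secondary alignment on the other genome are re-labelled
``ambiguous``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import pysam

from .genomes import DEFAULT_MITO_NAMES, GRAFT, HOST, MITO, NUCLEAR, ContigIndex
from .simulate import FRAGMENT_COLUMNS

AMBIGUOUS = "ambiguous"


def index_from_alignments(
    path: str | Path,
    graft_prefix: str = "graft",
    host_prefix: str = "host",
    mito_names: frozenset[str] = DEFAULT_MITO_NAMES,
) -> ContigIndex:
    """Build a contig index from a SAM/BAM header by name convention.

    Contigs are assigned to graft/host by name prefix and to the
    mitochondrial compartment by membership in ``mito_names``.
    """
    entries: dict[str, tuple[str, str, int]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for name, length in zip(fh.references, fh.lengths):
            if name.startswith(graft_prefix):
                genome = GRAFT
            elif name.startswith(host_prefix):
                genome = HOST
            else:
                raise ValueError(f"contig {name!r} matches neither genome prefix")
            compartment = MITO if name in mito_names else NUCLEAR
            entries[name] = (genome, compartment, int(length))
    graft_names = [c for c, (g, _, _) in entries.items() if g == GRAFT]
    host_names = [c for c, (g, _, _) in entries.items() if g == HOST]
    homolog: dict[str, str] = {}
    for a, b in zip(graft_names, host_names):
        homolog[a] = b
        homolog[b] = a
    return ContigIndex(entries=entries, homolog=homolog)


@dataclass(frozen=True)
class FragmentRecord:
    """One cfDNA fragment; interval is 0-based half-open."""

    read_id: str
    genome: str
    compartment: str
    contig: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def extract_fragments(
    path: str | Path,
    index: ContigIndex,
    min_mapq: int = 20,
    require_proper: bool = True,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Read a SAM/BAM into the canonical fragment table.

    Returns ``(fragments, skipped)`` where ``skipped`` counts records
    dropped as unpaired/not-proper, low-MAPQ, or lacking a positive
    template length (only the leftmost mate of each pair is counted).
    Unknown contigs raise ``ValueError``.
    """
    skipped = {"unpaired": 0, "not_proper": 0, "low_mapq": 0, "secondary": 0, "unmapped": 0}
    rows: list[tuple] = []
    secondary_genomes: dict[str, set[str]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.reference_name is None:
                skipped["unmapped"] += 1
                continue
            contig = rec.reference_name
            if contig not in index:
                raise ValueError(f"unknown contig {contig!r} in {path}")
            if rec.is_secondary or rec.is_supplementary:
                skipped["secondary"] += 1
                secondary_genomes.setdefault(rec.query_name, set()).add(index.genome_of(contig))
                continue
            if not rec.is_paired:
                skipped["unpaired"] += 1
                continue
            if require_proper and not rec.is_proper_pair:
                skipped["not_proper"] += 1
                continue
            if rec.mapping_quality < min_mapq:
                skipped["low_mapq"] += 1
                continue
            tlen = rec.template_length
            if tlen <= 0:  # rightmost mate (or undefined): already counted at the left one
                continue
            start = rec.reference_start
            rows.append(
                (rec.query_name, index.genome_of(contig), index.compartment_of(contig),
                 contig, start, start + tlen, tlen)
            )
    frags = pd.DataFrame(rows, columns=[c for c in FRAGMENT_COLUMNS if c != "ambiguous"])
    # a template is ambiguous when it also aligns on a genome other than its primary's
    frags["ambiguous"] = [
        bool(secondary_genomes.get(rid, set()) - {genome})
        for rid, genome in zip(frags["read_id"], frags["genome"])
    ]
    frags.loc[frags["ambiguous"], "genome"] = AMBIGUOUS
    return frags, skipped


def write_fragment_table(frags: pd.DataFrame, path: str | Path) -> None:
    frags.to_csv(path, sep="\t", index=False)


def read_fragment_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
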