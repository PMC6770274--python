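"""Toy two-genome (graft tumor + host normal) references.

A xenograft blood sample mixes cfDNA from the engrafted human tumor
("graft") and the mouse host ("host").  Analyses downstream only need
alignment coordinates, so the reference here is a pair of small random
genomes whose contig names encode genome and compartment membership:
``graft_chr1`` (nuclear), ``graft_chrM`` (mitochondrial), and the host
equivalents.  Real chromosome-scale references are deliberately out of
scope; every coordinate-level behaviour is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from .errors import ConfigError

NUCLEAR = "nuclear"
MITO = "mito"
GRAFT = "graft"
HOST = "host"

#: contig names treated as mitochondrial unless a GenomeSpec says otherwise
DEFAULT_MITO_NAMES = frozenset({"chrM", "MT", "graft_chrM", "host_chrM"})

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class GenomeSpec:
    """One genome of the two-genome reference.

    Parameters
    ----------
    label
        ``"graft"`` (tumor of origin) or ``"host"``.
    nuclear_contigs
        Tuples of ``(name, length_bp)``; lengths must be positive.
    mito_contig
        ``(name, length_bp)``; the human mitochondrial genome is
        16 569 bp, the default here.  Lengths below 1 kb are rejected.
    """

    label: str
    nuclear_contigs: tuple[tuple[str, int], ...]
    mito_contig: tuple[str, int] = ("chrM", 16569)

    def __post_init__(self):
        if self.label not in (GRAFT, HOST):
            raise ConfigError(f"genome label must be graft or host, got {self.label!r}")
        object.__setattr__(self, "nuclear_contigs", tuple((str(n), int(l)) for n, l in self.nuclear_contigs))
        object.__setattr__(self, "mito_contig", (str(self.mito_contig[0]), int(self.mito_contig[1])))
        for name, length in self.nuclear_contigs:
            if length <= 0:
                raise ConfigError(f"contig {name} has non-positive length {length}")
        if self.mito_contig[1] < 1000:
            raise ConfigError(f"mitochondrial contig length {self.mito_contig[1]} < 1000 bp")

    def contigs(self) -> Iterator[tuple[str, int, str]]:
        """Yield ``(name, length, compartment)`` for every contig."""
        for name, length in self.nuclear_contigs:
            yield name, length, NUCLEAR
        yield self.mito_contig[0], self.mito_contig[1], MITO


@dataclass(frozen=True)
class ContigIndex:
    """Maps contig name -> (genome label, compartment, length) for both genomes.

    Also records, for each contig, its positional homolog in the other
    genome (same rank among that genome's contigs) so the simulator can
    place cross-species secondary alignments.
    """

    entries: dict[str, tuple[str, str, int]]
    homolog: dict[str, str] = field(default_factory=dict)

    def genome_of(self, contig: str) -> str:
        return self.entries[contig][0]

    def compartment_of(self, contig: str) -> str:
        return self.entries[contig][1]

    def length_of(self, contig: str) -> int:
        return self.entries[contig][2]

    def contigs(self, genome: str | None = None, compartment: str | None = None) -> list[str]:
        return [
            c
            for c, (g, comp, _) in self.entries.items()
            if (genome is None or g == genome) and (compartment is None or comp == compartment)
        ]

    def __contains__(self, contig: str) -> bool:
        return contig in self.entries


def build_contig_index(graft: GenomeSpec, host: GenomeSpec) -> ContigIndex:
    """Combine two genome specs into one lookup table.

    Raises :class:`ConfigError` if any contig name occurs twice across
    the pair — the combined-reference trick requires unique names.
    """
    entries: dict[str, tuple[str, str, int]] = {}
    for spec in (graft, host):
        for name, length, compartment in spec.contigs():
            if name in entries:
                raise ConfigError(f"duplicate contig name across genomes: {name!r}")
            entries[name] = (spec.label, compartment, length)
    homolog: dict[str, str] = {}
    graft_names = [n for n, _, _ in graft.contigs()]
    host_names = [n for n, _, _ in host.contigs()]
    for a, b in zip(graft_names, host_names):
        homolog[a] = b
        homolog[b] = a
    return ContigIndex(entries=entries, homolog=homolog)


def default_genome_pair(
    nuclear_length: int = 2_000_000,
    host_mito_length: int = 16299,
) -> tuple[GenomeSpec, GenomeSpec]:
    """The demo reference: one nuclear contig plus chrM per genome.

    The host mito default (16 299 bp) mirrors the mouse mitochondrial
    genome size; the graft keeps the human 16 569 bp.
    """
    graft = GenomeSpec(
        label=GRAFT,
        nuclear_contigs=(("graft_chr1", nuclear_length),),
        mito_contig=("graft_chrM", 16569),
    )
    host = GenomeSpec(
        label=HOST,
        nuclear_contigs=(("host_chr1", nuclear_length),),
        mito_contig=("host_chrM", host_mito_length),
    )
    return graft, host


def _random_sequence(length: int, rng: np.random.Generator) -> bytes:
    return _BASES[rng.integers(0, 4, size=length)].tobytes()


def build_toy_genomes(
    graft: GenomeSpec,
    host: GenomeSpec,
    seed: int,
    outdir: str | Path,
) -> tuple[dict[str, Path], ContigIndex]:
    """Write deterministic random FASTA files for both genomes.

    Bases are drawn i.i.d. uniform over ACGT, so GC content converges to
    0.5; each contig gets its own seed stream derived from ``seed`` and
    its rank, making output bytes a pure function of (specs, seed).

    Returns ``({label: fasta_path}, ContigIndex)``.
    """
    index = build_contig_index(graft, host)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    rank = 0
    for spec in (graft, host):
        path = outdir / f"{spec.label}.fa"
        with open(path, "wb") as fh:
            for name, length, _ in spec.contigs():
                rng = np.random.default_rng([int(seed), rank])
                rank += 1
                fh.write(f">{name}\n".encode())
                seq = _random_sequence(length, rng)
                for i in range(0, length, 60):
                    fh.write(seq[i : i + 60])
                    fh.write(b"\n")
        paths[spec.label] = path
    return paths, index
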