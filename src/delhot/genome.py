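"""Genome model and SNP-array coordinate lattice.

A :class:`GenomeModel` describes the simulated genome: a small set of
autosomes, an Illumina-like SNP lattice (~1 SNP / 10 kb), deletion hotspot
intervals with their intensity multipliers, and optional gene/exon models
used for coding-overlap annotation.  Every deletion call in the pipeline is
expressed on the :class:`SnpMap` lattice, because array data can only
resolve breakpoints to the first and last affected SNP.

Coordinates are 0-based half-open throughout; intensity TSV files use
1-based positions and are converted on read/write.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Hotspot",
    "Gene",
    "SnpMap",
    "GenomeModel",
    "build_genome_model",
    "default_genome_model",
    "default_autosomes",
    "default_hotspots",
    "default_genes",
]


@dataclass(frozen=True)
class Hotspot:
    """A deletion hotspot interval with its rate multiplier (>= 1)."""

    chrom: str
    start: int
    end: int
    multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"hotspot end must exceed start: {self}")
        if self.multiplier < 1:
            raise ValueError(f"hotspot multiplier must be >= 1: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Gene:
    """A gene model reduced to its exon intervals (0-based half-open)."""

    name: str
    chrom: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end in self.exons:
            if end <= start:
                raise ValueError(f"malformed exon in {self.name}: ({start}, {end})")
            if start < prev_end:
                raise ValueError(f"exons of {self.name} overlap or are unsorted")
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


class SnpMap:
    """Ordered SNP positions per autosome with a global index.

    SNP indices used by deletion calls are *global*: the per-chromosome
    position arrays are concatenated in chromosome order and indexed
    0..n_snps-1.  This makes boundary comparison between samples a pure
    integer comparison.
    """

    def __init__(self, chroms: list[str], positions: dict[str, np.ndarray]):
        self.chroms: tuple[str, ...] = tuple(chroms)
        self.positions: dict[str, np.ndarray] = {}
        offsets: dict[str, int] = {}
        off = 0
        for chrom in self.chroms:
            pos = np.asarray(positions[chrom], dtype=np.int64)
            if pos.ndim != 1:
                raise ValueError("positions must be 1-D per chromosome")
            if len(pos) and np.any(np.diff(pos) <= 0):
                raise ValueError(f"SNP positions on {chrom} must be strictly increasing")
            self.positions[chrom] = pos
            offsets[chrom] = off
            off += len(pos)
        self._offsets = offsets
        self.n_snps: int = off
        self._all_positions = (
            np.concatenate([self.positions[c] for c in self.chroms])
            if self.chroms
            else np.empty(0, dtype=np.int64)
        )

    def offset(self, chrom: str) -> int:
        return self._offsets[chrom]

    def chrom_slice(self, chrom: str) -> slice:
        off = self._offsets[chrom]
        return slice(off, off + len(self.positions[chrom]))

    def position(self, index: int) -> int:
        """bp position of a global SNP index."""
        return int(self._all_positions[index])

    def chrom_of(self, index: int) -> str:
        for chrom in self.chroms:
            sl = self.chrom_slice(chrom)
            if sl.start <= index < sl.stop:
                return chrom
        raise IndexError(index)

    def snps_in(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Global [lo, hi) index range of SNPs with start <= pos < end."""
        pos = self.positions[chrom]
        off = self._offsets[chrom]
        lo = int(np.searchsorted(pos, start, side="left"))
        hi = int(np.searchsorted(pos, end, side="left"))
        return off + lo, off + hi

    def __len__(self) -> int:
        return self.n_snps

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SnpMap):
            return NotImplemented
        return self.chroms == other.chroms and all(
            np.array_equal(self.positions[c], other.positions[c]) for c in self.chroms
        )


@dataclass(frozen=True)
class GenomeModel:
    """Autosomes, SNP lattice, hotspots and gene models for one simulation."""

    autosomes: tuple[tuple[str, int], ...]
    snp_spacing: int
    hotspots: tuple[Hotspot, ...]
    genes: tuple[Gene, ...]
    snp_map: SnpMap = field(compare=False)

    def __post_init__(self) -> None:
        if self.snp_spacing <= 0:
            raise ValueError("snp_spacing must be > 0")
        lengths = dict(self.autosomes)
        for _, length in self.autosomes:
            if length <= 0:
                raise ValueError("chromosome lengths must be > 0")
        by_chrom: dict[str, list[Hotspot]] = {}
        for hs in self.hotspots:
            if hs.chrom not in lengths:
                raise ValueError(f"hotspot on unknown chromosome {hs.chrom}")
            if hs.start < 0 or hs.end > lengths[hs.chrom]:
                raise ValueError(f"hotspot outside chromosome: {hs}")
            by_chrom.setdefault(hs.chrom, []).append(hs)
        for chrom, spots in by_chrom.items():
            spots = sorted(spots, key=lambda h: h.start)
            for a, b in zip(spots, spots[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping hotspots on {chrom}: {a} / {b}")
        for gene in self.genes:
            if gene.chrom not in lengths:
                raise ValueError(f"gene {gene.name} on unknown chromosome {gene.chrom}")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.autosomes)

    @property
    def genome_length(self) -> int:
        return sum(length for _, length in self.autosomes)

    @property
    def hotspot_length(self) -> int:
        return sum(h.length for h in self.hotspots)

    def hotspot_at(self, chrom: str, pos: int) -> Hotspot | None:
        for hs in self.hotspots:
            if hs.chrom == chrom and hs.start <= pos < hs.end:
                return hs
        return None


def build_genome_model(
    autosomes: list[tuple[str, int]],
    snp_spacing: int = 10_000,
    hotspots: list[Hotspot] | None = None,
    genes: list[Gene] | None = None,
    seed: int | np.random.Generator = 0,
    jitter: float = 0.45,
) -> GenomeModel:
    """Construct a genome model with an evenly spaced, jittered SNP lattice.

    SNP *i* on a chromosome sits at ``(i + 0.5) * spacing`` plus a uniform
    jitter of at most ``jitter * spacing`` (jitter < 0.5 keeps the lattice
    strictly increasing).  Deterministic for a given seed.
    """
    if snp_spacing <= 0:
        raise ValueError("snp_spacing must be > 0")
    if not 0 <= jitter < 0.5:
        raise ValueError("jitter must be in [0, 0.5)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    positions: dict[str, np.ndarray] = {}
    for chrom, length in autosomes:
        n = int(length // snp_spacing)
        base = (np.arange(n) + 0.5) * snp_spacing
        wobble = rng.uniform(-jitter, jitter, size=n) * snp_spacing
        pos = np.clip(np.round(base + wobble).astype(np.int64), 0, length - 1)
        positions[chrom] = pos
    snp_map = SnpMap([c for c, _ in autosomes], positions)
    return GenomeModel(
        autosomes=tuple((c, int(l)) for c, l in autosomes),
        snp_spacing=int(snp_spacing),
        hotspots=tuple(hotspots or ()),
        genes=tuple(genes or ()),
        snp_map=snp_map,
    )


MB = 1_000_000


def default_autosomes() -> list[tuple[str, int]]:
    """Desk-scale mini-genome: 4 autosomes of 30 Mb each."""
    return [(f"chr{i}", 30 * MB) for i in range(1, 5)]


def default_hotspots() -> list[Hotspot]:
    """Thirteen hotspots totalling 7.0 Mb, length-weighted mean multiplier ~54.

    The set emulates the study design this package reproduces: ~13 regions of
    0.4-0.6 Mb covering about 7 Mb in total, enriched ~50-fold on average
    with the two most extreme regions above 100-fold.
    """
    spec = [
        ("chr1", 3.0, 3.6, 100), ("chr1", 9.0, 9.6, 50),
        ("chr1", 15.0, 15.5, 40), ("chr1", 21.0, 21.4, 30),
        ("chr2", 4.0, 4.6, 100), ("chr2", 11.0, 11.5, 50),
        ("chr2", 18.0, 18.4, 40), ("chr2", 24.0, 24.6, 30),
        ("chr3", 5.0, 5.6, 60), ("chr3", 13.0, 13.5, 50),
        ("chr3", 20.0, 20.6, 40),
        ("chr4", 6.0, 6.6, 60), ("chr4", 16.0, 16.5, 30),
    ]
    return [
        Hotspot(c, int(s * MB), int(e * MB), float(m)) for c, s, e, m in spec
    ]


def default_genes() -> list[Gene]:
    """Synthetic gene models overlapping a subset of the default hotspots.

    Emulates the observation that hotspot genes are long with sparse exons:
    ``longGeneA`` spans the chr1 3.0-3.6 Mb hotspot with two exons inside;
    ``parkinLike`` has small exons of which numbers 3 and 4 fall inside the
    chr2 4.0-4.6 Mb hotspot; the remaining hotspots carry no gene.
    """
    exonsA = tuple((int(s * MB), int(s * MB) + 2_000) for s in
                   (2.80, 3.15, 3.45, 3.80, 4.10))
    exonsB = tuple((int(s * MB), int(s * MB) + 1_500) for s in
                   (3.80, 3.95, 4.15, 4.45, 4.80, 5.00))
    exonsC = tuple((int(s * MB), int(s * MB) + 3_000) for s in (12.0, 12.3, 12.6))
    return [
        Gene("longGeneA", "chr1", exonsA),
        Gene("parkinLike", "chr2", exonsB),
        Gene("bystanderC", "chr3", exonsC),
    ]


def default_genome_model(seed: int = 0) -> GenomeModel:
    """The default study genome: mini-genome, 13 hotspots, 3 gene models."""
    return build_genome_model(
        default_autosomes(),
        snp_spacing=10_000,
        hotspots=default_hotspots(),
        genes=default_genes(),
        seed=seed,
    )
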