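"""Poisson genome-bin scan for rare-deletion hotspots.

The genome is tiled into fixed, non-overlapping bins of 0.6 Mb (the unit
length adopted for hotspot regions); each independent event is assigned to
exactly one bin by its midpoint.  Under the null of unbiased placement the
number of bins containing exactly k events follows B * Poisson(k; N/B), and
bins holding >= 3 independent events (merged when adjacent) are called
hotspots.  Enrichment folds compare the per-bp event density inside a
region with the genome-wide density outside all hotspot regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence

import numpy as np
from scipy import stats

from .genome import GenomeModel

__all__ = [
    "BinCounts",
    "PoissonExpectation",
    "HotspotRegion",
    "HotspotTable",
    "bin_counts",
    "poisson_expectation",
    "call_hotspots",
    "enrichment_fold",
    "scan_hotspots",
]


class _Interval(Protocol):
    chrom: str
    start: int
    end: int


def _midpoint(event: _Interval) -> int:
    return (event.start + event.end) // 2


@dataclass
class BinCounts:
    """Per-chromosome event counts on a fixed tiling."""

    bin_size: int
    counts: dict[str, np.ndarray]
    partial_last_bin: dict[str, bool]

    @property
    def n_bins(self) -> int:
        return sum(len(c) for c in self.counts.values())

    @property
    def total_events(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))

    def histogram(self) -> dict[int, int]:
        """Observed number of bins holding exactly k events."""
        all_counts = np.concatenate(list(self.counts.values()))
        values, freq = np.unique(all_counts, return_counts=True)
        return {int(v): int(f) for v, f in zip(values, freq)}


def bin_counts(
    events: Sequence[_Interval],
    chrom_lengths: dict[str, int] | GenomeModel,
    bin_size: int = 600_000,
) -> BinCounts:
    """Count events per fixed 0.6 Mb bin, assigning each by its midpoint.

    The tiling starts at position 0 on every chromosome; a final partial
    bin is kept and flagged.  An event spanning a bin boundary contributes
    to the single bin holding its midpoint.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    if isinstance(chrom_lengths, GenomeModel):
        chrom_lengths = chrom_lengths.chrom_lengths
    counts: dict[str, np.ndarray] = {}
    partial: dict[str, bool] = {}
    for chrom, length in chrom_lengths.items():
        n = int(np.ceil(length / bin_size))
        counts[chrom] = np.zeros(n, dtype=np.int64)
        partial[chrom] = length % bin_size != 0
    for event in events:
        if event.chrom not in counts:
            raise ValueError(f"event on unknown chromosome {event.chrom}")
        counts[event.chrom][_midpoint(event) // bin_size] += 1
    return BinCounts(bin_size=bin_size, counts=counts, partial_last_bin=partial)


@dataclass(frozen=True)
class PoissonExpectation:
    """Null expectation for bins holding exactly k events."""

    n_events: int
    n_bins: int
    k: int
    lam: float
    expected_bins: float
    bin_tail_p: float  # per-bin P(X >= k)


def poisson_expectation(n_events: int, n_bins: int, k: int) -> PoissonExpectation:
    """Expected number of bins with exactly k events under unbiased placement.

    lam = N/B; expected = B * e^-lam * lam^k / k!; also returns the per-bin
    upper tail P(X >= k).
    """
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    lam = n_events / n_bins
    return PoissonExpectation(
        n_events=n_events,
        n_bins=n_bins,
        k=k,
        lam=lam,
        expected_bins=float(n_bins * stats.poisson.pmf(k, lam)),
        bin_tail_p=float(stats.poisson.sf(k - 1, lam)),
    )


@dataclass
class HotspotRegion:
    """A called hotspot: merged qualifying bins with event-derived limits."""

    chrom: str
    start: int  # min start of member events
    end: int  # max end of member events
    bin_start: int  # bp start of first qualifying bin
    bin_end: int  # bp end of last qualifying bin
    n_independent: int
    tail_p: float
    bonferroni_p: float
    fold: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def call_hotspots(
    counts: BinCounts,
    events: Sequence[_Interval],
    min_events: int = 3,
) -> list[HotspotRegion]:
    """Call bins holding >= min_events independent events, merging neighbours.

    Region limits are the min start / max end over member events (the
    convention used for reporting observed hotspot boundaries); the raw bin
    extent is kept alongside.  The per-region p-value is the per-bin
    Poisson upper tail at the scan's overall density, with a Bonferroni
    column for reference (no correction is applied when calling).
    """
    n_events = len(events)
    n_bins = counts.n_bins
    lam = n_events / n_bins if n_bins else 0.0
    regions: list[HotspotRegion] = []
    for chrom, chrom_counts in counts.counts.items():
        hot = chrom_counts >= min_events
        if not hot.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([0], hot.view(np.int8), [0]))))
        for a, b in zip(edges[::2], edges[1::2]):
            bin_start = int(a) * counts.bin_size
            bin_end = int(b) * counts.bin_size
            members = [
                ev
                for ev in events
                if ev.chrom == chrom and bin_start <= _midpoint(ev) < bin_end
            ]
            n = len(members)
            tail = float(stats.poisson.sf(n - 1, lam * (b - a)))
            regions.append(
                HotspotRegion(
                    chrom=chrom,
                    start=min(ev.start for ev in members),
                    end=max(ev.end for ev in members),
                    bin_start=bin_start,
                    bin_end=bin_end,
                    n_independent=n,
                    tail_p=tail,
                    bonferroni_p=min(1.0, tail * n_bins),
                )
            )
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def enrichment_fold(
    regions: list[HotspotRegion],
    events: Sequence[_Interval],
    chrom_lengths: dict[str, int] | GenomeModel,
) -> tuple[list[float], float]:
    """Per-region and length-weighted average enrichment folds.

    fold = (events per bp inside the region) / (events per bp genome-wide
    excluding all hotspot regions).  Membership is by event midpoint, the
    same convention as binning.  Regions are measured over their bin extent
    so short regions are not inflated by the event-limit convention.
    """
    if not regions:
        raise ValueError("no hotspot regions given")
    if isinstance(chrom_lengths, GenomeModel):
        chrom_lengths = chrom_lengths.chrom_lengths
    genome_len = sum(chrom_lengths.values())

    def members(region: HotspotRegion) -> int:
        return sum(
            1
            for ev in events
            if ev.chrom == region.chrom
            and region.bin_start <= _midpoint(ev) < region.bin_end
        )

    inside = [members(r) for r in regions]
    inside_len = sum(r.bin_end - r.bin_start for r in regions)
    outside_events = len(events) - sum(inside)
    outside_len = genome_len - inside_len
    background_density = outside_events / outside_len
    if background_density == 0:
        raise ValueError("zero background event density")
    folds = []
    for region, n_in in zip(regions, inside):
        density = n_in / (region.bin_end - region.bin_start)
        fold = density / background_density
        region.fold = fold
        folds.append(fold)
    weights = [r.bin_end - r.bin_start for r in regions]
    average = float(np.average(folds, weights=weights))
    return folds, average


@dataclass
class HotspotTable:
    """The scan summary: bins, null expectations, observed histogram, regions."""

    bin_size: int
    n_bins: int
    n_events: int
    lam: float
    expected: dict[int, float]
    observed: dict[int, int]
    regions: list[HotspotRegion] = field(default_factory=list)
    average_fold: float | None = None


def scan_hotspots(
    events: Sequence[_Interval],
    chrom_lengths: dict[str, int] | GenomeModel,
    bin_size: int = 600_000,
    min_events: int = 3,
    k_max: int = 8,
) -> HotspotTable:
    """Run the full scan: bin, compare to Poisson, call and rank hotspots."""
    counts = bin_counts(events, chrom_lengths, bin_size)
    n_bins = counts.n_bins
    n_events = len(events)
    expected = {
        k: poisson_expectation(n_events, n_bins, k).expected_bins
        for k in range(k_max + 1)
    }
    regions = call_hotspots(counts, events, min_events)
    table = HotspotTable(
        bin_size=bin_size,
        n_bins=n_bins,
        n_events=n_events,
        lam=n_events / n_bins,
        expected=expected,
        observed=counts.histogram(),
        regions=regions,
    )
    if regions and n_events:
        try:
            _, table.average_fold = enrichment_fold(regions, events, chrom_lengths)
        except ValueError:
            table.average_fold = None
    return table
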