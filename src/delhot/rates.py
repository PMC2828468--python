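"""Mutation-rate arithmetic, deletion length statistics and exon annotation.

The de novo rate generalises "d de novo events among n offspring over L bp
of hotspot sequence" to a per-generation, per-chromosome, per-unit-length
rate r = d / (2n) * (u / L) — two parental chromosomes can contribute at an
autosomal locus.  The literature-style projection for a disease-gene
hotspot (modelled on the DMD major deletion hotspot) multiplies an
incidence by the de novo, deletion and in-hotspot fractions, then doubles
to account for purely intronic deletions that never ascertain.  Rates are
presented to one significant figure alongside full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .genome import Gene
from .hotspots import HotspotRegion, _Interval, _midpoint

__all__ = [
    "RateResult",
    "DmdProjection",
    "LengthStats",
    "round_sig",
    "de_novo_rate",
    "incidence_hotspot_rate",
    "rate_ratio",
    "length_statistics",
    "exon_overlap",
    "cohort_table",
]


def round_sig(x: float, digits: int = 1) -> float:
    """Round to ``digits`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round(x, digits - 1 - exponent)


@dataclass(frozen=True)
class RateResult:
    """A per-generation, per-chromosome, per-unit-length deletion rate."""

    d: int
    n_individuals: int
    chromosomes_per_locus: int
    hotspot_length: float  # bp
    unit: float  # bp
    rate: float

    @property
    def rate_one_sig_fig(self) -> float:
        return round_sig(self.rate, 1)

    @property
    def per_bp(self) -> float:
        return self.rate / self.unit


def de_novo_rate(
    d: int,
    n_individuals: int,
    hotspot_length: float,
    unit: float = 600_000.0,
    chromosomes_per_locus: int = 2,
) -> RateResult:
    """Rate of de novo deletion per generation per chromosome per unit length.

    r = d / (chromosomes * n) * (unit / hotspot_length).  Linear in d and in
    the unit; e.g. 5 events among 440 offspring over 7 Mb of hotspots give
    4.87e-4 per generation per chromosome per 0.6 Mb.
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    if n_individuals <= 0 or unit <= 0 or chromosomes_per_locus <= 0:
        raise ValueError("n_individuals, unit and chromosomes must be > 0")
    if hotspot_length <= 0:
        raise ValueError("hotspot_length must be > 0")
    rate = d / (chromosomes_per_locus * n_individuals) * (unit / hotspot_length)
    return RateResult(
        d=d,
        n_individuals=n_individuals,
        chromosomes_per_locus=chromosomes_per_locus,
        hotspot_length=float(hotspot_length),
        unit=float(unit),
        rate=rate,
    )


@dataclass(frozen=True)
class DmdProjection:
    """Ascertainable and projected total de novo deletion frequency."""

    ascertainable: float
    projected_total: float
    unit: float = 700_000.0

    def as_rate(self, label_unit: float | None = None) -> RateResult:
        """The projected total expressed as a RateResult for ratio taking."""
        unit = label_unit if label_unit is not None else self.unit
        return RateResult(
            d=0,
            n_individuals=1,
            chromosomes_per_locus=1,
            hotspot_length=unit,
            unit=unit,
            rate=self.projected_total,
        )


def incidence_hotspot_rate(
    incidence: float,
    f_de_novo: float,
    f_deletion: float,
    f_hotspot: float,
    intronic_multiplier: float = 2.0,
    unit: float = 700_000.0,
) -> DmdProjection:
    """Project a hotspot de novo deletion frequency from disease epidemiology.

    ascertainable = incidence * f_de_novo * f_deletion * f_hotspot; the
    total doubles it (deletions lying wholly within introns are never
    ascertained clinically but are about as frequent).  For the DMD major
    hotspot: 1/3500 * 1/3 * 0.60 * 2/3 = 3.8e-5 (~4e-5) ascertainable and
    ~8e-5 projected per generation per chromosome per 0.7 Mb.
    """
    if incidence <= 0:
        raise ValueError("incidence must be > 0")
    for name, f in (("f_de_novo", f_de_novo), ("f_deletion", f_deletion),
                    ("f_hotspot", f_hotspot)):
        if not 0 <= f <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    ascertainable = incidence * f_de_novo * f_deletion * f_hotspot
    return DmdProjection(
        ascertainable=ascertainable,
        projected_total=ascertainable * intronic_multiplier,
        unit=unit,
    )


def rate_ratio(r1: RateResult, r2: RateResult) -> float:
    """Unit-length-normalised ratio of two rates: (r1/u1) / (r2/u2)."""
    if r2.rate == 0:
        raise ValueError("cannot take a ratio against a zero rate")
    return r1.per_bp / r2.per_bp


@dataclass(frozen=True)
class LengthStats:
    group: str
    n: int
    mean: float
    median: float
    sd: float
    fraction_in_range: float
    range_bp: tuple[float, float]


def length_statistics(
    lengths_by_group: dict[str, Sequence[float]],
    length_range: tuple[float, float] = (20_000.0, 200_000.0),
) -> tuple[dict[str, LengthStats], dict[str, float]]:
    """Length summaries per group plus a 2x2 chi-square on the in-range counts.

    Returns per-group mean/median/SD and the fraction of lengths inside
    ``length_range`` (inclusive), and — when exactly two groups are given —
    the chi-square statistic and p-value for in-range vs out-of-range
    counts, both without (primary) and with the Yates continuity
    correction.
    """
    lo, hi = length_range
    if hi <= lo:
        raise ValueError("length_range must be increasing")
    summaries: dict[str, LengthStats] = {}
    in_out: list[list[int]] = []
    for group, lengths in lengths_by_group.items():
        arr = np.asarray(lengths, dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {group!r} is empty")
        in_range = int(((arr >= lo) & (arr <= hi)).sum())
        summaries[group] = LengthStats(
            group=group,
            n=int(arr.size),
            mean=float(arr.mean()),
            median=float(np.median(arr)),
            sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            fraction_in_range=in_range / arr.size,
            range_bp=(lo, hi),
        )
        in_out.append([in_range, int(arr.size) - in_range])
    tests: dict[str, float] = {}
    if len(in_out) == 2:
        table = np.array(in_out)
        if table.sum(axis=0).min() > 0 and table.sum(axis=1).min() > 0:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            chi2_y, p_y, _, _ = stats.chi2_contingency(table, correction=True)
            tests = {
                "chi2": float(chi2),
                "p": float(p),
                "chi2_yates": float(chi2_y),
                "p_yates": float(p_y),
            }
    return summaries, tests


def _exon_trees(genes: Sequence[Gene]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for gene in genes:
        tree = trees.setdefault(gene.chrom, IntervalTree())
        for start, end in gene.exons:
            tree[start:end] = gene.name
    return trees


def exon_overlap(
    events: Sequence[_Interval],
    genes: Sequence[Gene],
) -> list[bool]:
    """Flag each event as coding-affected (intersects >= 1 exon interval).

    Intervals are 0-based half-open on both sides, so an event abutting an
    exon end-to-end does not count as overlap.
    """
    trees = _exon_trees(genes)
    flags: list[bool] = []
    for event in events:
        tree = trees.get(event.chrom)
        flags.append(bool(tree.overlap(event.start, event.end)) if tree else False)
    return flags


def _region_gene(region: HotspotRegion, genes: Sequence[Gene]) -> str:
    for gene in genes:
        if gene.chrom != region.chrom:
            continue
        span_start, span_end = gene.span
        if span_start < region.bin_end and region.bin_start < span_end:
            return gene.name
    return "none"


def cohort_table(
    events_by_cohort: dict[str, Sequence[_Interval]],
    regions: Sequence[HotspotRegion],
    genes: Sequence[Gene] = (),
):
    """Per-hotspot summary table in "n (n_coding)" style.

    One row per hotspot region: location label, limits in Mb (1 decimal),
    resident gene (or "none"), and per cohort the independent event count
    with the coding-affected count in parentheses — "(na)" when the region
    carries no gene.  Returns a pandas DataFrame.
    """
    import pandas as pd

    rows = []
    for region in regions:
        gene = _region_gene(region, genes)
        row = {
            "region": f"{region.chrom}:{region.bin_start // 1_000_000}Mb",
            "limits_mb": f"{region.start / 1e6:.1f}-{region.end / 1e6:.1f}",
            "gene": gene,
        }
        for cohort, events in events_by_cohort.items():
            members = [
                ev
                for ev in events
                if ev.chrom == region.chrom
                and region.bin_start <= _midpoint(ev) < region.bin_end
            ]
            if gene == "none":
                row[cohort] = f"{len(members)} (na)"
            else:
                coding = sum(exon_overlap(members, genes)) if members else 0
                row[cohort] = f"{len(members)} ({coding})"
        rows.append(row)
    return pd.DataFrame(rows)
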