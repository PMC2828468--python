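"""Collapsing identical calls into independent events and rarity filtering.

Deletion calls whose first and last array SNPs agree (within an optional
tolerance) are treated as the same mutational event observed in several
carriers; boundary-distinct calls count as independent events.  The rarity
restriction keeps only events seen in at most ``max_carriers`` individuals
within any single cohort (an absolute count, matching the study's "1 or 2
individuals per sample of about 500" rule for cohorts of 440-640 alike);
recurrence *across* cohorts never drops an event.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .calling import DeletionCall
from .trios import match_boundaries

__all__ = ["IndependentEvent", "collapse_identical", "frequency_filter"]


@dataclass
class IndependentEvent:
    """A boundary-deduplicated deletion with its carrier list."""

    chrom: str
    first_snp: int
    last_snp: int
    start: int
    end: int
    carriers: list[tuple[str, str]]  # (cohort, sample)

    def __post_init__(self) -> None:
        if not self.carriers:
            raise ValueError("an event needs at least one carrier")

    @property
    def n_carriers(self) -> Counter:
        return Counter(cohort for cohort, _ in self.carriers)

    @property
    def length(self) -> int:
        return self.end - self.start


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def collapse_identical(
    calls: list[DeletionCall],
    tolerance: int = 0,
    cohort: str | dict[str, str] = "cohort",
) -> list[IndependentEvent]:
    """Partition calls into independent events by boundary identity.

    With tolerance 0, calls sharing (chrom, first_snp, last_snp) form one
    event.  With tolerance > 0 the partition is the transitive closure of
    pairwise :func:`match_boundaries`.  ``cohort`` is either a single label
    or a sample -> cohort mapping.  The sum of class sizes equals the input
    count, and collapsing is idempotent.
    """
    if not calls:
        return []
    label = (lambda s: cohort[s]) if isinstance(cohort, dict) else (lambda s: cohort)
    order = sorted(range(len(calls)), key=lambda i: (calls[i].chrom, calls[i].first_snp))
    uf = _UnionFind(len(calls))
    for oi in range(len(order)):
        i = order[oi]
        for oj in range(oi + 1, len(order)):
            j = order[oj]
            if calls[j].chrom != calls[i].chrom:
                break
            if calls[j].first_snp - calls[i].first_snp > tolerance:
                break
            if match_boundaries(calls[i], calls[j], tolerance):
                uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(len(calls)):
        groups.setdefault(uf.find(i), []).append(i)
    events: list[IndependentEvent] = []
    for members in groups.values():
        rep = calls[min(members, key=lambda i: (calls[i].first_snp, calls[i].sample))]
        events.append(
            IndependentEvent(
                chrom=rep.chrom,
                first_snp=rep.first_snp,
                last_snp=rep.last_snp,
                start=rep.start,
                end=rep.end,
                carriers=[(label(calls[i].sample), calls[i].sample) for i in members],
            )
        )
    events.sort(key=lambda e: (e.chrom, e.first_snp))
    return events


def frequency_filter(
    events: list[IndependentEvent],
    max_carriers: int = 2,
) -> tuple[list[IndependentEvent], list[IndependentEvent]]:
    """Keep events carried by at most ``max_carriers`` individuals per cohort.

    An event exceeding the bound in *any* single cohort is dropped as a
    common (or repeat-mediated recurrent) deletion; everything kept is
    labelled rare by construction.  Returns (kept, dropped).
    """
    kept: list[IndependentEvent] = []
    dropped: list[IndependentEvent] = []
    for event in events:
        if any(n > max_carriers for n in event.n_carriers.values()):
            dropped.append(event)
        else:
            kept.append(event)
    return kept, dropped
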