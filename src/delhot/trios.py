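"""Two-round parent/child cross-verification of deletion calls.

Round 1 walks every affirmed offspring call: if a parental strict call has
the same first/last SNP (within a tolerance, default 0) the deletion is
*transmitted*; otherwise both parents are re-scanned at the locus with the
relaxed threshold, and a successful rescue in either parent also means
transmitted (the strict call in the parent was a false negative).  Only
when both parents show no qualifying signal at strict and relaxed
thresholds is the call *de novo*.

Round 2 walks every affirmed parental call: if the offspring already has an
affirmed call overlapping the locus the transmission was counted in round
1; otherwise the offspring is re-scanned, a successful rescue adds a
recovered transmitted deletion (flagged when the same event was already
known from another trio), and a failed rescue labels the parental deletion
*non-transmitted*.  Non-transmitted counting is per parental chromosome: a
deletion present in both parents is two candidate transmissions.

The ledger's counts support two estimators: the standalone per-genome call
sensitivity s (fraction of deletions known to be present in a genome that
the strict caller called there, pooled over parents and offspring) and the
combined two-generation sensitivity S = 1 - (1 - s)^2, since a deletion is
found whenever the strict caller fires in either carrier and targeted
rescue in the other generation is nearly perfect.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

from .calling import CallerConfig, DeletionCall, rescan_locus
from .genome import SnpMap
from .synthetic_cohort import IntensityTrack, Trio

__all__ = [
    "TrioLedger",
    "SensitivityEstimate",
    "CrossTab",
    "Round1Record",
    "Round1Result",
    "Round2Record",
    "Round2Result",
    "match_boundaries",
    "classify_round1",
    "classify_round2",
    "compile_ledger",
    "combined_sensitivity",
    "estimate_sensitivity",
    "estimate_true_counts",
    "TrueCountEstimate",
]


def match_boundaries(a: DeletionCall, b: DeletionCall, tolerance: int = 0) -> bool:
    """True iff both first and last SNP indices agree within ``tolerance``.

    Calls on different chromosomes never match.  Symmetric by construction.
    """
    if a.chrom != b.chrom:
        return False
    return (
        abs(a.first_snp - b.first_snp) <= tolerance
        and abs(a.last_snp - b.last_snp) <= tolerance
    )


@dataclass
class Round1Record:
    """Classification of one affirmed offspring call."""

    family: str
    call: DeletionCall
    label: str  # transmitted | de_novo
    mechanism: str | None = None  # matched | rescued (transmitted only)
    carrier_parent: str | None = None
    parent_strict_overlap: bool = False  # carrier parent had a strict call here
    rescued_parent_call: DeletionCall | None = None


@dataclass
class Round1Result:
    records: list[Round1Record] = field(default_factory=list)
    skipped_trios: list[str] = field(default_factory=list)

    @property
    def transmitted(self) -> list[Round1Record]:
        return [r for r in self.records if r.label == "transmitted"]

    @property
    def de_novo(self) -> list[Round1Record]:
        return [r for r in self.records if r.label == "de_novo"]


@dataclass
class Round2Record:
    """Fate of one affirmed parental call."""

    family: str
    parent: str
    call: DeletionCall
    outcome: str  # matched_in_offspring | recovered | non_transmitted
    offspring_strict_overlap: bool = False
    recovered_call: DeletionCall | None = None
    already_known: bool = False


@dataclass
class Round2Result:
    records: list[Round2Record] = field(default_factory=list)

    @property
    def recovered(self) -> list[Round2Record]:
        return [r for r in self.records if r.outcome == "recovered"]

    @property
    def non_transmitted(self) -> list[Round2Record]:
        return [r for r in self.records if r.outcome == "non_transmitted"]

    @property
    def matched(self) -> list[Round2Record]:
        return [r for r in self.records if r.outcome == "matched_in_offspring"]


def _rescue_region(
    call: DeletionCall, snp_map: SnpMap, pad_snps: int
) -> tuple[int, int]:
    """bp region around a call, padded by whole SNPs and clipped to the chromosome."""
    sl = snp_map.chrom_slice(call.chrom)
    lo = max(sl.start, call.first_snp - pad_snps)
    hi = min(sl.stop - 1, call.last_snp + pad_snps)
    return snp_map.position(lo), snp_map.position(hi) + 1


def classify_round1(
    calls_by_sample: dict[str, list[DeletionCall]],
    tracks: dict[str, IntensityTrack],
    snp_map: SnpMap,
    trios: list[Trio],
    config: CallerConfig = CallerConfig(),
) -> Round1Result:
    """Label each affirmed offspring call transmitted or de novo.

    ``calls_by_sample`` must hold the strict caller's affirmed calls for
    every QC-passed sample; trios with a missing parent (or child) track
    are skipped with a warning.
    """
    result = Round1Result()
    for trio in trios:
        members = (trio.child, trio.father, trio.mother)
        if any(m not in tracks for m in members):
            warnings.warn(f"trio {trio.family}: missing track, skipped", stacklevel=2)
            result.skipped_trios.append(trio.family)
            continue
        for call in calls_by_sample.get(trio.child, []):
            record = Round1Record(family=trio.family, call=call, label="de_novo")
            for parent in (trio.father, trio.mother):
                p_calls = calls_by_sample.get(parent, [])
                strict_overlap = any(
                    pc.overlaps(call.chrom, call.start, call.end) for pc in p_calls
                )
                matched = any(
                    match_boundaries(call, pc, config.match_tolerance)
                    for pc in p_calls
                )
                if matched:
                    record.label = "transmitted"
                    record.mechanism = "matched"
                    record.carrier_parent = parent
                    record.parent_strict_overlap = True
                    break
                if strict_overlap and not record.parent_strict_overlap:
                    # strict signal is there but boundaries disagree; rescue
                    # below will confirm, keep the flag for the sensitivity
                    # cross-tab
                    record.parent_strict_overlap = True
            if record.label == "de_novo":
                start, end = _rescue_region(call, snp_map, config.rescue_pad_snps)
                for parent in (trio.father, trio.mother):
                    rescue = rescan_locus(
                        tracks[parent],
                        snp_map,
                        call.chrom,
                        start,
                        end,
                        threshold=config.relaxed_threshold,
                        min_run=config.rescue_min_run,
                    )
                    if rescue is not None:
                        record.label = "transmitted"
                        record.mechanism = "rescued"
                        record.carrier_parent = parent
                        record.rescued_parent_call = rescue
                        break
            result.records.append(record)
    return result


def classify_round2(
    calls_by_sample: dict[str, list[DeletionCall]],
    tracks: dict[str, IntensityTrack],
    snp_map: SnpMap,
    trios: list[Trio],
    round1: Round1Result,
    config: CallerConfig = CallerConfig(),
) -> Round2Result:
    """Trace each affirmed parental call into the offspring.

    A parental call whose offspring already shows an overlapping affirmed
    call was handled in round 1; otherwise the offspring track is re-scanned
    at the locus.  Recovered events whose boundaries coincide with a
    transmitted event already found in *another* trio are flagged
    ``already_known`` so independent counting does not double-book them.
    """
    skipped = set(round1.skipped_trios)
    known: dict[tuple[str, int, int], set[str]] = {}
    for rec in round1.transmitted:
        known.setdefault(rec.call.boundaries, set()).add(rec.family)
    result = Round2Result()
    for trio in trios:
        if trio.family in skipped:
            continue
        child_calls = calls_by_sample.get(trio.child, [])
        for parent in (trio.father, trio.mother):
            for call in calls_by_sample.get(parent, []):
                overlap = any(
                    cc.overlaps(call.chrom, call.start, call.end)
                    for cc in child_calls
                )
                if overlap:
                    result.records.append(
                        Round2Record(
                            family=trio.family,
                            parent=parent,
                            call=call,
                            outcome="matched_in_offspring",
                            offspring_strict_overlap=True,
                        )
                    )
                    continue
                start, end = _rescue_region(call, snp_map, config.rescue_pad_snps)
                rescue = rescan_locus(
                    tracks[trio.child],
                    snp_map,
                    call.chrom,
                    start,
                    end,
                    threshold=config.relaxed_threshold,
                    min_run=config.rescue_min_run,
                )
                if rescue is not None:
                    families = known.get(call.boundaries, set())
                    result.records.append(
                        Round2Record(
                            family=trio.family,
                            parent=parent,
                            call=call,
                            outcome="recovered",
                            recovered_call=rescue,
                            already_known=bool(families - {trio.family}),
                        )
                    )
                else:
                    result.records.append(
                        Round2Record(
                            family=trio.family,
                            parent=parent,
                            call=call,
                            outcome="non_transmitted",
                        )
                    )
    return result


@dataclass
class TrioLedger:
    """Bookkeeping counts of the two-round verification.

    Derived fields: ``transmitted_total = matched_in_parent +
    rescued_in_parent`` and ``offspring_total_final = transmitted_total +
    de_novo + rescued_in_offspring`` (recovered events already known from
    other trios stay in the total; they are only collapsed when counting
    independent events).
    """

    offspring_affirmed_independent: int = 0
    offspring_affirmed_total: int = 0
    matched_in_parent: int = 0
    rescued_in_parent: int = 0
    transmitted_total: int = 0
    transmitted_independent: int = 0
    de_novo: int = 0
    parent_affirmed_independent: int = 0
    parent_affirmed_total: int = 0
    matched_in_offspring: int = 0
    rescued_in_offspring: int = 0
    rescued_already_known: int = 0
    offspring_total_final: int = 0
    offspring_independent_final: int = 0
    nontransmitted_independent: int = 0
    nontransmitted_total: int = 0

    @classmethod
    def from_components(cls, **counts: int) -> "TrioLedger":
        """Build a ledger from component counts, deriving the totals."""
        ledger = cls(**counts)
        ledger.transmitted_total = ledger.matched_in_parent + ledger.rescued_in_parent
        ledger.offspring_total_final = (
            ledger.transmitted_total + ledger.de_novo + ledger.rescued_in_offspring
        )
        ledger.validate()
        return ledger

    def validate(self) -> None:
        for name, value in asdict(self).items():
            if value < 0:
                raise ValueError(f"negative count {name}={value}")
        if self.transmitted_total != self.matched_in_parent + self.rescued_in_parent:
            raise ValueError("transmitted_total != matched + rescued in parent")
        expected = self.transmitted_total + self.de_novo + self.rescued_in_offspring
        if self.offspring_total_final != expected:
            raise ValueError("offspring_total_final inconsistent")
        if self.rescued_already_known > self.rescued_in_offspring:
            raise ValueError("rescued_already_known exceeds rescued_in_offspring")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TrioLedger":
        ledger = cls(**json.loads(text))
        ledger.validate()
        return ledger


def compile_ledger(
    round1: Round1Result,
    round2: Round2Result,
    parent_calls: list[DeletionCall],
    tolerance: int = 0,
) -> TrioLedger:
    """Fill every ledger count from the two rounds' records.

    ``parent_calls`` are the affirmed strict calls of all QC-passed parents
    (the pool round 2 walked).  Independent counts collapse boundary-
    identical calls at the given tolerance.
    """
    from .independence import collapse_identical

    child_calls = [r.call for r in round1.records]
    transmitted_calls = [r.call for r in round1.transmitted]
    recovered_calls = [r.recovered_call for r in round2.recovered]
    final_calls = child_calls + recovered_calls
    nt_calls = [r.call for r in round2.non_transmitted]
    ledger = TrioLedger.from_components(
        offspring_affirmed_independent=len(collapse_identical(child_calls, tolerance)),
        offspring_affirmed_total=len(child_calls),
        matched_in_parent=sum(1 for r in round1.transmitted if r.mechanism == "matched"),
        rescued_in_parent=sum(1 for r in round1.transmitted if r.mechanism == "rescued"),
        transmitted_independent=len(collapse_identical(transmitted_calls, tolerance)),
        de_novo=len(round1.de_novo),
        parent_affirmed_independent=len(collapse_identical(parent_calls, tolerance)),
        parent_affirmed_total=len(parent_calls),
        matched_in_offspring=len(round2.matched),
        rescued_in_offspring=len(round2.recovered),
        rescued_already_known=sum(1 for r in round2.recovered if r.already_known),
        offspring_independent_final=len(collapse_identical(final_calls, tolerance)),
        nontransmitted_independent=len(collapse_identical(nt_calls, tolerance)),
        nontransmitted_total=len(nt_calls),
    )
    return ledger


def combined_sensitivity(s: float) -> float:
    """Two-generation sensitivity S = 1 - (1 - s)^2 for standalone s."""
    if not 0 < s <= 1:
        raise ValueError("standalone sensitivity must be in (0, 1]")
    return 1.0 - (1.0 - s) ** 2


@dataclass(frozen=True)
class SensitivityEstimate:
    standalone: float
    combined: float
    method: str

    def __post_init__(self) -> None:
        if not 0 < self.standalone <= 1:
            raise ValueError("standalone sensitivity must be in (0, 1]")


@dataclass(frozen=True)
class CrossTab:
    """Carrier/called tallies for the pooled sensitivity estimator.

    ``parent_known`` transmitted deletions are by definition present in the
    carrier parent; ``parent_called`` of them drew a strict call there.
    ``offspring_known`` parental deletions were verified present in the
    child (matched or rescued); ``offspring_called`` of them drew a strict
    call in the child.
    """

    parent_known: int
    parent_called: int
    offspring_known: int
    offspring_called: int

    @classmethod
    def from_rounds(cls, round1: Round1Result, round2: Round2Result) -> "CrossTab":
        return cls(
            parent_known=len(round1.transmitted),
            parent_called=sum(1 for r in round1.transmitted if r.parent_strict_overlap),
            offspring_known=len(round2.matched) + len(round2.recovered),
            offspring_called=len(round2.matched),
        )


def estimate_sensitivity(source: TrioLedger | CrossTab) -> SensitivityEstimate:
    """Estimate standalone and combined sensitivity from verification counts.

    From a :class:`CrossTab`, s pools strict-called carriers over both
    generations.  From a :class:`TrioLedger` the boundary-matched counts
    stand in for strict detection (an approximation when boundary precision
    is imperfect).  S = 1 - (1 - s)^2 in either case.
    """
    if isinstance(source, TrioLedger):
        known = (
            source.transmitted_total
            + source.matched_in_offspring
            + source.rescued_in_offspring
        )
        called = source.matched_in_parent + source.matched_in_offspring
        method = "ledger"
    else:
        known = source.parent_known + source.offspring_known
        called = source.parent_called + source.offspring_called
        method = "crosstab"
    if known == 0:
        raise ValueError("no transmitted events: sensitivity undefined")
    s = called / known
    return SensitivityEstimate(
        standalone=s, combined=combined_sensitivity(s), method=method
    )


@dataclass(frozen=True)
class TrueCountEstimate:
    detected: int
    sensitivity: float
    estimate: float
    rounded: int


def estimate_true_counts(detected: int, sensitivity: float) -> TrueCountEstimate:
    """Correct a detected independent count for imperfect sensitivity.

    Returns detected / sensitivity both at full precision and rounded to
    the nearest 10 for presentation.
    """
    if not 0 < sensitivity <= 1:
        raise ValueError("sensitivity must be in (0, 1]")
    if detected < 0:
        raise ValueError("detected count must be >= 0")
    estimate = detected / sensitivity
    return TrueCountEstimate(
        detected=detected,
        sensitivity=sensitivity,
        estimate=estimate,
        rounded=int(round(estimate / 10.0)) * 10,
    )
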