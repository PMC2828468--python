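"""End-to-end orchestration of the trio deletion-hotspot analysis.

``run_study`` wires the stages together on a (simulated or loaded) cohort:
strict calling -> sample QC and trio completion -> two-round verification
-> independence collapse and rarity filter -> Poisson hotspot scan ->
sensitivity and true-count estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .calling import CallerConfig, DeletionCall, SampleQcReport, call_deletions, qc_filter_samples
from .genome import GenomeModel
from .hotspots import HotspotTable, scan_hotspots
from .independence import IndependentEvent, collapse_identical, frequency_filter
from .synthetic_cohort import Cohort, TrioDesign, NoiseModel, simulate_cohort
from .trios import (
    CrossTab,
    Round1Result,
    Round2Result,
    SensitivityEstimate,
    TrioLedger,
    TrueCountEstimate,
    classify_round1,
    classify_round2,
    compile_ledger,
    estimate_sensitivity,
    estimate_true_counts,
)

__all__ = ["StudyResult", "run_study", "analyse_cohort"]


@dataclass
class StudyResult:
    cohort: Cohort
    config: CallerConfig
    calls_by_sample: dict[str, list[DeletionCall]]
    qc_reports: list[SampleQcReport]
    trios_kept: list
    round1: Round1Result
    round2: Round2Result
    ledger: TrioLedger
    events: list[IndependentEvent]
    rare_events: list[IndependentEvent]
    dropped_events: list[IndependentEvent] = field(default_factory=list)
    hotspot_table: HotspotTable | None = None
    sensitivity: SensitivityEstimate | None = None
    true_transmitted: TrueCountEstimate | None = None
    true_nontransmitted: TrueCountEstimate | None = None


def analyse_cohort(
    cohort: Cohort,
    config: CallerConfig = CallerConfig(),
    cohort_label: str = "cohort",
    bin_size: int = 600_000,
    min_hotspot_events: int = 3,
    max_carriers: int = 2,
) -> StudyResult:
    """Run calling, QC, verification, rarity filtering and the hotspot scan."""
    smap = cohort.model.snp_map
    calls_by_sample = {
        sample: call_deletions(track, smap, config.strict_threshold, config.min_run)
        for sample, track in cohort.tracks.items()
    }
    kept_samples, qc_reports = qc_filter_samples(
        calls_by_sample, config.max_calls_per_sample
    )
    kept = set(kept_samples)
    trios_kept = [
        t for t in cohort.trios
        if t.child in kept and t.father in kept and t.mother in kept
    ]
    qc_calls = {s: c for s, c in calls_by_sample.items() if s in kept}
    round1 = classify_round1(qc_calls, cohort.tracks, smap, trios_kept, config)
    round2 = classify_round2(qc_calls, cohort.tracks, smap, trios_kept, round1, config)
    parent_samples = {t.father for t in trios_kept} | {t.mother for t in trios_kept}
    parent_calls = [c for s in sorted(parent_samples) for c in qc_calls.get(s, [])]
    ledger = compile_ledger(round1, round2, parent_calls, config.match_tolerance)
    # independent events among final offspring deletions (transmitted + de
    # novo + recovered), then the rarity restriction, then the scan
    final_calls = [r.call for r in round1.records] + [
        r.recovered_call for r in round2.recovered
    ]
    events = collapse_identical(final_calls, config.match_tolerance, cohort_label)
    rare_events, dropped = frequency_filter(events, max_carriers)
    hotspot_table = (
        scan_hotspots(rare_events, cohort.model, bin_size, min_hotspot_events)
        if rare_events
        else None
    )
    sensitivity = None
    true_transmitted = None
    true_nontransmitted = None
    if round1.transmitted:
        sensitivity = estimate_sensitivity(CrossTab.from_rounds(round1, round2))
        true_transmitted = estimate_true_counts(
            ledger.offspring_independent_final, sensitivity.combined
        )
        if ledger.nontransmitted_independent:
            true_nontransmitted = estimate_true_counts(
                ledger.nontransmitted_independent, sensitivity.standalone
            )
    return StudyResult(
        cohort=cohort,
        config=config,
        calls_by_sample=calls_by_sample,
        qc_reports=qc_reports,
        trios_kept=trios_kept,
        round1=round1,
        round2=round2,
        ledger=ledger,
        events=events,
        rare_events=rare_events,
        dropped_events=dropped,
        hotspot_table=hotspot_table,
        sensitivity=sensitivity,
        true_transmitted=true_transmitted,
        true_nontransmitted=true_nontransmitted,
    )


def run_study(
    seed: int,
    model: GenomeModel | None = None,
    design: TrioDesign | None = None,
    noise: NoiseModel | None = None,
    config: CallerConfig = CallerConfig(),
    **analyse_kwargs,
) -> StudyResult:
    """Simulate a cohort from one seed and analyse it end to end."""
    cohort = simulate_cohort(seed, model=model, design=design, noise=noise)
    return analyse_cohort(cohort, config, **analyse_kwargs)
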