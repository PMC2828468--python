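import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from delhot import (
    CallerConfig,
    CrossTab,
    TrioLedger,
    call_deletions,
    classify_round1,
    classify_round2,
    combined_sensitivity,
    compile_ledger,
    estimate_sensitivity,
    estimate_true_counts,
    match_boundaries,
    run_study,
)
from delhot.calling import DeletionCall
from delhot.synthetic_cohort import Trio

from conftest import make_map, make_track


def _call(first, last, sample="s", chrom="chr1", spacing=10_000, provenance="called"):
    return DeletionCall(
        sample=sample,
        chrom=chrom,
        first_snp=first,
        last_snp=last,
        start=(first + 1) * spacing,
        end=(last + 1) * spacing + 1,
        n_snps=last - first + 1,
        mean_logr=-0.7,
        provenance=provenance,
    )


class TestMatchBoundaries:
    def test_identical_indices_match(self):
        assert match_boundaries(_call(10, 14), _call(10, 14))

    def test_one_snp_shift_needs_tolerance(self):
        a, b = _call(10, 14), _call(11, 14)
        assert not match_boundaries(a, b, tolerance=0)
        assert match_boundaries(a, b, tolerance=1)

    def test_disjoint_calls_never_match(self):
        assert not match_boundaries(_call(10, 14), _call(30, 34), tolerance=3)

    def test_different_chromosomes_never_match(self):
        assert not match_boundaries(_call(10, 14), _call(10, 14, chrom="chr2"))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        f1=st.integers(0, 50), s1=st.integers(2, 10),
        f2=st.integers(0, 50), s2=st.integers(2, 10),
        tol=st.integers(0, 3),
    )
    def test_symmetry(self, f1, s1, f2, s2, tol):
        a = _call(f1, f1 + s1)
        b = _call(f2, f2 + s2)
        assert match_boundaries(a, b, tol) == match_boundaries(b, a, tol)


def _mini_trio_setup(child_values, father_values, mother_values):
    """One trio on a 100-SNP chromosome; returns pieces for classification."""
    smap = make_map(100)
    tracks = {
        "c": make_track(child_values, "c"),
        "f": make_track(father_values, "f"),
        "m": make_track(mother_values, "m"),
    }
    config = CallerConfig()
    calls = {
        s: call_deletions(t, smap, config.strict_threshold, config.min_run)
        for s, t in tracks.items()
    }
    trios = [Trio("fam0", "c", "f", "m")]
    return calls, tracks, smap, trios, config


DEEP = -0.8  # well below the strict threshold
SHALLOW = -0.45  # between relaxed (-0.30) and strict (-0.575)


class TestClassifyRound1:
    def test_matched_parent_call_is_transmitted(self):
        child = np.zeros(100); child[40:45] = DEEP
        father = np.zeros(100); father[40:45] = DEEP
        calls, tracks, smap, trios, config = _mini_trio_setup(child, father, np.zeros(100))
        result = classify_round1(calls, tracks, smap, trios, config)
        (rec,) = result.records
        assert rec.label == "transmitted"
        assert rec.mechanism == "matched"
        assert rec.carrier_parent == "f"

    def test_shallow_parent_signal_is_rescued_transmitted(self):
        """A parental false negative is recovered by the relaxed re-scan."""
        child = np.zeros(100); child[40:45] = DEEP
        mother = np.zeros(100); mother[40:45] = SHALLOW
        calls, tracks, smap, trios, config = _mini_trio_setup(child, np.zeros(100), mother)
        assert calls["m"] == []  # below strict detection
        result = classify_round1(calls, tracks, smap, trios, config)
        (rec,) = result.records
        assert rec.label == "transmitted"
        assert rec.mechanism == "rescued"
        assert rec.carrier_parent == "m"
        assert rec.rescued_parent_call.provenance == "rescued"

    def test_flat_parents_mean_de_novo(self):
        child = np.zeros(100); child[40:45] = DEEP
        calls, tracks, smap, trios, config = _mini_trio_setup(
            child, np.zeros(100), np.zeros(100)
        )
        result = classify_round1(calls, tracks, smap, trios, config)
        (rec,) = result.records
        assert rec.label == "de_novo"

    def test_missing_parent_track_skips_trio_with_warning(self):
        child = np.zeros(100); child[40:45] = DEEP
        calls, tracks, smap, trios, config = _mini_trio_setup(
            child, np.zeros(100), np.zeros(100)
        )
        del tracks["f"]
        with pytest.warns(UserWarning, match="missing track"):
            result = classify_round1(calls, tracks, smap, trios, config)
        assert result.records == []
        assert result.skipped_trios == ["fam0"]


class TestClassifyRound2:
    def test_uncalled_offspring_deletion_recovered(self):
        father = np.zeros(100); father[60:66] = DEEP
        child = np.zeros(100); child[60:66] = SHALLOW
        calls, tracks, smap, trios, config = _mini_trio_setup(child, father, np.zeros(100))
        round1 = classify_round1(calls, tracks, smap, trios, config)
        result = classify_round2(calls, tracks, smap, trios, round1, config)
        (rec,) = result.records
        assert rec.outcome == "recovered"
        assert rec.recovered_call.sample == "c"
        assert not rec.already_known

    def test_flat_offspring_is_non_transmitted(self):
        father = np.zeros(100); father[60:66] = DEEP
        calls, tracks, smap, trios, config = _mini_trio_setup(
            np.zeros(100), father, np.zeros(100)
        )
        round1 = classify_round1(calls, tracks, smap, trios, config)
        result = classify_round2(calls, tracks, smap, trios, round1, config)
        (rec,) = result.records
        assert rec.outcome == "non_transmitted"

    def test_round1_matched_parent_call_not_reprocessed(self):
        child = np.zeros(100); child[40:45] = DEEP
        father = np.zeros(100); father[40:45] = DEEP
        calls, tracks, smap, trios, config = _mini_trio_setup(child, father, np.zeros(100))
        round1 = classify_round1(calls, tracks, smap, trios, config)
        result = classify_round2(calls, tracks, smap, trios, round1, config)
        (rec,) = result.records
        assert rec.outcome == "matched_in_offspring"
        assert result.recovered == []

    def test_deletion_in_both_parents_counts_two_candidates(self):
        father = np.zeros(100); father[60:66] = DEEP
        mother = np.zeros(100); mother[60:66] = DEEP
        calls, tracks, smap, trios, config = _mini_trio_setup(
            np.zeros(100), father, mother
        )
        round1 = classify_round1(calls, tracks, smap, trios, config)
        result = classify_round2(calls, tracks, smap, trios, round1, config)
        assert len(result.non_transmitted) == 2


class TestLedger:
    def test_transmitted_total_from_matched_plus_rescued(self):
        ledger = TrioLedger.from_components(matched_in_parent=274, rescued_in_parent=85)
        assert ledger.transmitted_total == 359

    def test_offspring_total_sums_transmitted_de_novo_and_recovered(self):
        ledger = TrioLedger.from_components(
            matched_in_parent=274,
            rescued_in_parent=85,
            de_novo=7,
            rescued_in_offspring=33,
            rescued_already_known=6,
        )
        assert ledger.transmitted_total == 359
        assert ledger.offspring_total_final == 399

    def test_empty_cohort_gives_all_zero_ledger(self):
        from delhot.trios import Round1Result, Round2Result

        ledger = compile_ledger(Round1Result(), Round2Result(), [])
        assert ledger == TrioLedger()

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            TrioLedger(transmitted_total=10, matched_in_parent=3,
                       rescued_in_parent=3).validate()

    def test_json_round_trip(self):
        ledger = TrioLedger.from_components(matched_in_parent=2, rescued_in_parent=1)
        assert TrioLedger.from_json(ledger.to_json()) == ledger


class TestSensitivity:
    @pytest.mark.parametrize(
        "s,expected", [(0.75, 0.9375), (1.0, 1.0), (0.5, 0.75)]
    )
    def test_combined_formula(self, s, expected):
        assert combined_sensitivity(s) == pytest.approx(expected)

    def test_crosstab_estimate(self):
        tab = CrossTab(
            parent_known=200, parent_called=150, offspring_known=200,
            offspring_called=150,
        )
        est = estimate_sensitivity(tab)
        assert est.standalone == pytest.approx(0.75)
        assert est.combined == pytest.approx(0.9375)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            estimate_sensitivity(CrossTab(0, 0, 0, 0))

    @pytest.mark.parametrize(
        "detected,s,estimate,rounded",
        [(270, 0.75, 360.0, 360), (368, 0.94, 391.489, 390), (100, 1.0, 100.0, 100)],
    )
    def test_true_count_correction(self, detected, s, estimate, rounded):
        result = estimate_true_counts(detected, s)
        assert result.estimate == pytest.approx(estimate, abs=0.01)
        assert result.rounded == rounded

    def test_zero_sensitivity_rejected(self):
        with pytest.raises(ValueError):
            estimate_true_counts(100, 0.0)


class TestPipelineRecovery:
    """End-to-end checks on simulated 440-trio cohorts."""

    @pytest.fixture(scope="class")
    @staticmethod
    def studies():
        return [run_study(seed=seed) for seed in range(6)]

    def test_every_affirmed_call_gets_exactly_one_label(self, studies):
        for res in studies:
            ledger = res.ledger
            assert (
                ledger.transmitted_total + ledger.de_novo
                == ledger.offspring_affirmed_total
            )

    def test_two_round_recovery_matches_combined_sensitivity(self, studies):
        """Recovered fraction of truly transmitted deletions ~ 1-(1-s)^2."""
        num = den = 0
        for res in studies:
            smap = res.cohort.model.snp_map
            found = [r.call for r in res.round1.records] + [
                r.recovered_call for r in res.round2.recovered
            ]
            for t in res.cohort.truth:
                if not t.sample.endswith("-c") or t.origin != "founder":
                    continue
                lo, hi = smap.snps_in(t.chrom, t.start, t.end)
                if hi - lo < 3:
                    continue
                den += 1
                num += any(
                    c.sample == t.sample and c.overlaps(t.chrom, t.start, t.end)
                    for c in found
                )
        assert den >= 2000
        assert abs(num / den - 0.9375) < 0.02

    def test_transmitted_events_rarely_labeled_de_novo(self, studies):
        wrong = transmitted = 0
        for res in studies:
            child_truth = [t for t in res.cohort.truth if t.sample.endswith("-c")]
            transmitted += sum(t.origin == "founder" for t in child_truth)
            for rec in res.round1.de_novo:
                c = rec.call
                if not any(
                    t.sample == c.sample
                    and t.origin.startswith("de_novo")
                    and t.start < c.end
                    and c.start < t.end
                    for t in child_truth
                ):
                    wrong += 1
        assert wrong / transmitted < 0.01

    def test_pooled_sensitivity_estimate_recovers_075(self, studies):
        known = called = 0
        for res in studies:
            tab = CrossTab.from_rounds(res.round1, res.round2)
            known += tab.parent_known + tab.offspring_known
            called += tab.parent_called + tab.offspring_called
        assert known >= 2000
        assert abs(called / known - 0.75) < 0.03

    def test_true_count_correction_recovers_truth_within_5_percent(self, studies):
        """Detected deletions / estimated S recovers the truth count."""
        est_total = truth_total = 0
        for res in studies:
            smap = res.cohort.model.snp_map
            found = [r.call for r in res.round1.records] + [
                r.recovered_call for r in res.round2.recovered
            ]
            eligible = detected = 0
            for t in res.cohort.truth:
                if not t.sample.endswith("-c") or t.origin != "founder":
                    continue
                lo, hi = smap.snps_in(t.chrom, t.start, t.end)
                if hi - lo < 3:
                    continue
                eligible += 1
                detected += any(
                    c.sample == t.sample and c.overlaps(t.chrom, t.start, t.end)
                    for c in found
                )
            truth_total += eligible
            est = estimate_true_counts(detected, res.sensitivity.combined)
            est_total += est.estimate
        assert truth_total >= 2000
        assert abs(est_total / truth_total - 1) < 0.05
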