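import numpy as np
import pytest
from scipy import stats

from delhot import (
    Hotspot,
    NoiseModel,
    TrioDesign,
    bin_counts,
    build_genome_model,
    render_logr,
    simulate_cohort,
    simulate_deletion_events,
    transmit_to_offspring,
)
from delhot.genome import MB
from delhot.synthetic_cohort import Trio

pytestmark = pytest.mark.filterwarnings("ignore::UserWarning")


class TestFounderEvents:
    def test_empty_founder_list_gives_empty_truth(self, flat_model):
        assert simulate_deletion_events(flat_model, TrioDesign(), 0, founders=[]) == []

    def test_invalid_rate_rejected(self, flat_model):
        with pytest.raises(ValueError):
            TrioDesign(founder_rate_per_bp=0.0)

    def test_homogeneous_null_passes_poisson_dispersion(self, flat_model):
        """Multiplier-1 bin counts are Poisson-dispersed in >= 18/20 seeds."""
        founders = [f"s{i}" for i in range(400)]
        design = TrioDesign()
        failures = 0
        for seed in range(20):
            truth = simulate_deletion_events(flat_model, design, seed, founders=founders)
            counts = np.concatenate(
                list(bin_counts(truth, flat_model, 600_000).counts.values())
            )
            disp = (len(counts) - 1) * counts.var(ddof=1) / counts.mean()
            if stats.chi2.sf(disp, len(counts) - 1) < 0.01:
                failures += 1
        assert failures <= 2

    def test_hotspot_density_recovers_multiplier_100(self):
        """A 100x hotspot carries ~100x the per-bp event density."""
        model = build_genome_model(
            [("chr1", 30 * MB)],
            hotspots=[Hotspot("chr1", 10 * MB, 11 * MB, 100.0)],
            seed=0,
        )
        founders = [f"s{i}" for i in range(600)]
        truth = simulate_deletion_events(model, TrioDesign(), 5, founders=founders)
        mids = np.array([(t.start + t.end) // 2 for t in truth])
        n_in = int(((mids >= 10 * MB) & (mids < 11 * MB)).sum())
        n_out = len(mids) - n_in
        fold = (n_in / MB) / (n_out / (29 * MB))
        # ~60 background and ~2000 hotspot events: 3 SE band on the ratio
        se = fold * np.sqrt(1 / max(n_in, 1) + 1 / max(n_out, 1))
        assert abs(fold - 100) < 3 * se

    def test_no_founder_carries_overlapping_deletions(self, model):
        founders = [f"s{i}" for i in range(300)]
        truth = simulate_deletion_events(model, TrioDesign(), 9, founders=founders)
        by_sample = {}
        for t in truth:
            by_sample.setdefault(t.sample, []).append(t)
        for dels in by_sample.values():
            dels.sort(key=lambda d: (d.chrom, d.start))
            for a, b in zip(dels, dels[1:]):
                assert a.chrom != b.chrom or a.end <= b.start

    def test_hotspot_lengths_hit_configured_20_200kb_fraction(self, model):
        """~68% of hotspot deletion lengths fall in 20-200 kb (+-5 points)."""
        founders = [f"s{i}" for i in range(700)]
        truth = simulate_deletion_events(model, TrioDesign(), 13, founders=founders)
        hs_lengths = np.array(
            [
                t.length
                for t in truth
                if model.hotspot_at(t.chrom, (t.start + t.end) // 2) is not None
            ]
        )
        assert len(hs_lengths) >= 500
        frac = ((hs_lengths >= 20_000) & (hs_lengths <= 200_000)).mean()
        assert abs(frac - 0.68) < 0.05

    def test_lengths_truncated_to_resolution_bounds(self, model):
        founders = [f"s{i}" for i in range(200)]
        truth = simulate_deletion_events(model, TrioDesign(), 3, founders=founders)
        lengths = np.array([t.length for t in truth])
        assert lengths.min() >= 3_000
        assert lengths.max() <= 2_000_000


class TestTransmission:
    def test_transmitted_fraction_is_half(self, model):
        """Mendelian coin: transmitted fraction 0.5 within 3 SE."""
        design = TrioDesign(de_novo_rate_per_mb=0.0)
        n = 4000
        trios = [Trio(f"f{i}", f"f{i}-c", f"f{i}-f", f"f{i}-m") for i in range(n)]
        founder_truth = [
            # one deletion per father
            _td(f"f{i}-f")
            for i in range(n)
        ]
        offspring = transmit_to_offspring(founder_truth, trios, design, model, 21)
        frac = len(offspring) / n
        se = np.sqrt(0.25 / n)
        assert abs(frac - 0.5) <= 3 * se
        # flags conserve the total
        assert sum(t.transmitted for t in founder_truth) == len(offspring)

    def test_de_novo_only_in_offspring_and_maternal_fraction(self, model):
        design = TrioDesign(de_novo_rate_per_mb=0.3, maternal_fraction=0.6)
        trios = [Trio(f"f{i}", f"f{i}-c", f"f{i}-f", f"f{i}-m") for i in range(1000)]
        offspring = transmit_to_offspring([], trios, design, model, 33)
        assert all(t.origin.startswith("de_novo") for t in offspring)
        assert all(t.sample.endswith("-c") for t in offspring)
        maternal = np.mean([t.origin == "de_novo_maternal" for t in offspring])
        n = len(offspring)
        assert n > 1000
        assert abs(maternal - 0.6) <= 3 * np.sqrt(0.24 / n)

    def test_default_de_novo_rate_expects_five_per_440_trio_cohort(self, model):
        """E[de novo] over 440 trios x 7 Mb of hotspots = 5, Poisson band."""
        design = TrioDesign()
        trios = [Trio(f"f{i}", f"f{i}-c", f"f{i}-f", f"f{i}-m") for i in range(440)]
        counts = [
            sum(
                1
                for t in transmit_to_offspring([], trios, design, model, seed)
                if t.origin.startswith("de_novo")
            )
            for seed in range(40)
        ]
        mean = np.mean(counts)
        # mean of 40 Poisson(5) draws: 3 SE band
        assert abs(mean - 5.0) <= 3 * np.sqrt(5.0 / 40)

    def test_de_novo_restricted_to_hotspots_by_default(self, model):
        design = TrioDesign(de_novo_rate_per_mb=0.5)
        trios = [Trio(f"f{i}", f"f{i}-c", f"f{i}-f", f"f{i}-m") for i in range(300)]
        offspring = transmit_to_offspring([], trios, design, model, 8)
        assert offspring
        for t in offspring:
            assert model.hotspot_at(t.chrom, (t.start + t.end) // 2) is not None


def _td(sample, chrom="chr1", start=5_000_000, end=5_100_000):
    from delhot import TruthDeletion

    return TruthDeletion(sample=sample, chrom=chrom, start=start, end=end)


class TestRenderLogr:
    def test_no_deletion_track_centred_on_zero(self, flat_model):
        tracks = render_logr([], flat_model, ["s1"], seed=0)
        values = tracks["s1"].values
        noise = NoiseModel()
        assert abs(values.mean()) < 4 * noise.sd_normal / np.sqrt(len(values))

    def test_deleted_snps_pulled_below_threshold(self, flat_model):
        """Mean LogR over a 10-SNP deletion sits well below -0.4."""
        truth = [_td("s1", start=1_000_000, end=1_100_000)]
        lo, hi = flat_model.snp_map.snps_in("chr1", 1_000_000, 1_100_000)
        assert hi - lo >= 8
        below = 0
        for seed in range(200):
            tracks = render_logr(truth, flat_model, ["s1"], seed=seed)
            if tracks["s1"].values[lo:hi].mean() < -0.4:
                below += 1
        assert below >= 195  # ~N(-0.66, sqrt(0.12^2 + 0.02^2/10)) below -0.4 w.p. >0.98

    def test_sub_three_snp_deletions_are_still_rendered(self, flat_model):
        truth = [_td("s1", start=1_000_000, end=1_012_000)]
        lo, hi = flat_model.snp_map.snps_in("chr1", 1_000_000, 1_012_000)
        assert 1 <= hi - lo < 3
        tracks = render_logr(truth, flat_model, ["s1"], seed=1)
        assert tracks["s1"].values[lo:hi].mean() < -0.3

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            NoiseModel(sd_normal=0.0)

    def test_unknown_chromosome_rejected(self, flat_model):
        with pytest.raises(ValueError, match="unknown chromosome"):
            render_logr([_td("s1", chrom="chrX")], flat_model, ["s1"], seed=0)


class TestCohortDeterminism:
    def test_identical_seeds_identical_cohorts(self):
        a = simulate_cohort(99, design=TrioDesign(n_trios=6))
        b = simulate_cohort(99, design=TrioDesign(n_trios=6))
        assert [(t.sample, t.chrom, t.start, t.end, t.origin, t.transmitted)
                for t in a.truth] == [
            (t.sample, t.chrom, t.start, t.end, t.origin, t.transmitted)
            for t in b.truth
        ]
        for sample in a.tracks:
            assert np.array_equal(a.tracks[sample].values, b.tracks[sample].values)

    def test_different_seeds_differ(self):
        a = simulate_cohort(1, design=TrioDesign(n_trios=2))
        b = simulate_cohort(2, design=TrioDesign(n_trios=2))
        assert not np.array_equal(
            a.tracks["fam0000-c"].values, b.tracks["fam0000-c"].values
        )

    def test_de_novo_events_appear_in_children_only(self, small_cohort):
        parents = {t.father for t in small_cohort.trios} | {
            t.mother for t in small_cohort.trios
        }
        for t in small_cohort.truth:
            if t.origin.startswith("de_novo"):
                assert t.sample not in parents
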