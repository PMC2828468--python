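import numpy as np
import pytest

from delhot import (
    TrioDesign,
    build_genome_model,
    default_genome_model,
    simulate_cohort,
)
from delhot.genome import MB, SnpMap
from delhot.synthetic_cohort import IntensityTrack


@pytest.fixture(scope="session")
def model():
    return default_genome_model(seed=0)


@pytest.fixture(scope="session")
def flat_model():
    """Mini-genome with no hotspots (homogeneous null)."""
    return build_genome_model(
        [(f"chr{i}", 30 * MB) for i in range(1, 5)], snp_spacing=10_000, seed=0
    )


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(11, design=TrioDesign(n_trios=20))


@pytest.fixture(scope="session")
def big_founder_set(model):
    """3000 founder genomes with rendered tracks, for calibration checks."""
    from delhot import render_logr, simulate_deletion_events

    founders = [f"s{i}" for i in range(3000)]
    rng = np.random.default_rng(20260930)
    truth = simulate_deletion_events(model, TrioDesign(), rng, founders=founders)
    tracks = render_logr(truth, model, founders, seed=rng)
    return founders, truth, tracks


def make_map(n: int, spacing: int = 10_000, chrom: str = "chr1") -> SnpMap:
    return SnpMap([chrom], {chrom: (np.arange(n) + 1) * spacing})


def make_track(values, sample="s1") -> IntensityTrack:
    return IntensityTrack(sample=sample, values=np.asarray(values, dtype=float))
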