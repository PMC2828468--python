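"""Synthetic trio-cohort generator with ground-truth deletions.

Generates parent-parent-child trios of SNP-array LogR tracks whose deletion
structure mirrors the assumptions of the downstream analysis:

* founder heterozygous deletions placed by an inhomogeneous Poisson process
  whose rate is multiplied inside hotspot intervals (up to ~100x background);
* lognormal deletion lengths — hotspot deletions with a 54 kb median and
  ~68% of lengths in 20-200 kb, background deletions with half that median
  and a heavier tail — truncated to [3 kb, 2 Mb] (array resolution bound);
* Mendelian transmission of each parental deletion with probability 1/2;
* de novo deletions in offspring at a configurable rate per hotspot-Mb,
  maternal with probability ``maternal_fraction`` (default 3/5);
* Gaussian LogR emission: copy-number-2 SNPs ~ N(0, sd_normal), deleted
  SNPs ~ N(mu_deleted, sd_deleted), so the rule-based caller has a
  calibrated per-genome sensitivity (~0.75 at the default threshold).

All randomness flows from a single master seed through
``numpy.random.SeedSequence.spawn``, so identical seeds give byte-identical
cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import MB, GenomeModel

__all__ = [
    "TrioDesign",
    "NoiseModel",
    "TruthDeletion",
    "IntensityTrack",
    "Trio",
    "Cohort",
    "simulate_deletion_events",
    "transmit_to_offspring",
    "render_logr",
    "simulate_cohort",
    "DEFAULT_DE_NOVO_RATE_PER_MB",
]

#: Default de novo rate per child per hotspot-Mb, chosen so that a cohort of
#: 440 children with 7 Mb of hotspot sequence expects 5 de novo deletions.
DEFAULT_DE_NOVO_RATE_PER_MB = 5.0 / (440 * 7.0)


@dataclass(frozen=True)
class TrioDesign:
    """Cohort design parameters.

    Parameters
    ----------
    n_trios:
        Number of father-mother-child trios.
    call_sensitivity:
        The per-genome standalone call sensitivity the default noise model
        and caller threshold are calibrated to (documentation of the study
        condition; the realised sensitivity comes from the noise model).
    de_novo_rate_per_mb:
        Expected de novo deletions per child per Mb of hotspot sequence.
    de_novo_genome_wide_rate_per_mb:
        Optional additional de novo rate per child per Mb applied across the
        whole genome (0 restricts de novo events to hotspots).
    maternal_fraction:
        Probability that a de novo deletion arises on the maternal
        chromosome (default 3/5).
    founder_rate_per_bp:
        Background rate of founder deletions per bp; multiplied inside
        hotspots.  The default yields ~1.1 deletions per founder genome on
        the default mini-genome, i.e. ~0.9 deletions spanning >= 3 SNPs per
        transmitted genome.
    hotspot_length_median / hotspot_length_sigma:
        Lognormal length parameters for hotspot deletions (bp, log-sd).
    background_length_median / background_length_sigma:
        Same for background deletions (half the median, heavier tail).
    min_length / max_length:
        Truncation bounds for deletion lengths.
    """

    n_trios: int = 440
    call_sensitivity: float = 0.75
    de_novo_rate_per_mb: float = DEFAULT_DE_NOVO_RATE_PER_MB
    de_novo_genome_wide_rate_per_mb: float = 0.0
    maternal_fraction: float = 0.6
    founder_rate_per_bp: float = 2.4e-9
    hotspot_length_median: float = 54_000.0
    hotspot_length_sigma: float = 1.15
    background_length_median: float = 27_000.0
    background_length_sigma: float = 1.40
    min_length: float = 3_000.0
    max_length: float = 2_000_000.0

    def __post_init__(self) -> None:
        if self.n_trios < 0:
            raise ValueError("n_trios must be >= 0")
        if not 0 < self.call_sensitivity <= 1:
            raise ValueError("call_sensitivity must be in (0, 1]")
        if not 0 <= self.maternal_fraction <= 1:
            raise ValueError("maternal_fraction must be in [0, 1]")
        if self.founder_rate_per_bp <= 0:
            raise ValueError("founder_rate_per_bp must be > 0")


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian LogR emission parameters.

    A heterozygously deleted segment renders as a *cluster*: every SNP in
    the segment shares one per-(deletion, sample) intensity shift
    ``delta ~ N(0, sd_shift)`` — emulating sample- and region-level array
    artifacts (DNA quality, intensity waves) that raise or depress a whole
    segment — plus small independent per-SNP noise ``sd_deleted``.  Copy-
    number-2 SNPs draw N(0, sd_normal) independently.

    The shift makes strict-caller detection behave like a per-genome coin,
    nearly independent of deletion length, and independent between parent
    and child for the same event: exactly the regime in which a two-
    generation cross-check has combined sensitivity 1 - (1 - s)^2 while a
    targeted relaxed re-scan almost always confirms a true carrier.  The
    defaults are calibrated jointly with the caller's strict threshold to
    a standalone per-genome sensitivity of ~0.75.
    """

    mu_deleted: float = -0.66
    sd_deleted: float = 0.02
    sd_shift: float = 0.12
    sd_normal: float = 0.15

    def __post_init__(self) -> None:
        if self.sd_deleted <= 0 or self.sd_normal <= 0 or self.sd_shift < 0:
            raise ValueError("noise standard deviations must be > 0")
        if self.mu_deleted >= 0:
            raise ValueError("mu_deleted must be < 0")


@dataclass
class TruthDeletion:
    """A ground-truth heterozygous deletion (0-based half-open bp)."""

    sample: str
    chrom: str
    start: int
    end: int
    origin: str = "founder"  # founder | de_novo_maternal | de_novo_paternal
    transmitted: bool | None = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("deletion end must exceed start")
        if self.origin not in ("founder", "de_novo_maternal", "de_novo_paternal"):
            raise ValueError(f"unknown origin {self.origin!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class IntensityTrack:
    """Per-SNP LogR values for one sample, aligned to a SnpMap."""

    sample: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("LogR values must be finite")


@dataclass(frozen=True)
class Trio:
    family: str
    child: str
    father: str
    mother: str


@dataclass
class Cohort:
    """A simulated trio cohort: genome, pedigree, truth set and tracks."""

    model: GenomeModel
    design: TrioDesign
    noise: NoiseModel
    trios: list[Trio]
    truth: list[TruthDeletion]
    tracks: dict[str, IntensityTrack]

    @property
    def samples(self) -> list[str]:
        return list(self.tracks)

    def truth_of(self, sample: str) -> list[TruthDeletion]:
        return [t for t in self.truth if t.sample == sample]


def _segment_table(model: GenomeModel) -> list[tuple[str, int, int, float]]:
    """Chromosomes partitioned into (chrom, start, end, multiplier) segments."""
    segments: list[tuple[str, int, int, float]] = []
    for chrom, length in model.autosomes:
        cursor = 0
        spots = sorted(
            (h for h in model.hotspots if h.chrom == chrom), key=lambda h: h.start
        )
        for hs in spots:
            if hs.start > cursor:
                segments.append((chrom, cursor, hs.start, 1.0))
            segments.append((chrom, hs.start, hs.end, hs.multiplier))
            cursor = hs.end
        if cursor < length:
            segments.append((chrom, cursor, length, 1.0))
    return segments


def _draw_length(
    design: TrioDesign, in_hotspot: bool, rng: np.random.Generator
) -> int:
    if in_hotspot:
        median, sigma = design.hotspot_length_median, design.hotspot_length_sigma
    else:
        median, sigma = design.background_length_median, design.background_length_sigma
    for _ in range(1000):
        length = float(np.exp(rng.normal(np.log(median), sigma)))
        if design.min_length <= length <= design.max_length:
            return int(round(length))
    raise RuntimeError("length rejection sampling failed")  # pragma: no cover


def _place_deletion(
    sample: str,
    chrom: str,
    mid: int,
    in_hotspot: bool,
    model: GenomeModel,
    design: TrioDesign,
    rng: np.random.Generator,
    origin: str = "founder",
) -> TruthDeletion:
    length = _draw_length(design, in_hotspot, rng)
    chrom_len = model.chrom_lengths[chrom]
    start = max(0, mid - length // 2)
    end = min(chrom_len, start + length)
    start = max(0, end - length)
    return TruthDeletion(sample=sample, chrom=chrom, start=start, end=end, origin=origin)


def _overlaps_any(d: TruthDeletion, existing: list[TruthDeletion]) -> bool:
    return any(
        e.chrom == d.chrom and e.start < d.end and d.start < e.end for e in existing
    )


def simulate_deletion_events(
    model: GenomeModel,
    design: TrioDesign,
    seed: int | np.random.Generator = 0,
    founders: list[str] | None = None,
) -> list[TruthDeletion]:
    """Draw founder deletions from the inhomogeneous point process.

    Each founder's deletion count is Poisson with mean
    ``rate * sum(segment_length * multiplier)``; deletion midpoints are
    drawn segment-weighted, lengths from the hotspot or background length
    model depending on where the midpoint falls.  Overlapping deletions
    within one founder are re-drawn, so no founder carries more than one
    event at a locus (heterozygous events only).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if founders is None:
        founders = [
            f"fam{i:04d}-{role}" for i in range(design.n_trios) for role in ("f", "m")
        ]
    segments = _segment_table(model)
    weights = np.array([(e - s) * m for _, s, e, m in segments], dtype=float)
    total_intensity = design.founder_rate_per_bp * weights.sum()
    probs = weights / weights.sum()
    truth: list[TruthDeletion] = []
    for founder in founders:
        n = int(rng.poisson(total_intensity))
        mine: list[TruthDeletion] = []
        for _ in range(n):
            for _attempt in range(100):
                seg = segments[int(rng.choice(len(segments), p=probs))]
                chrom, s, e, mult = seg
                mid = int(rng.integers(s, e))
                d = _place_deletion(
                    founder, chrom, mid, mult > 1.0, model, design, rng
                )
                if not _overlaps_any(d, mine):
                    mine.append(d)
                    break
        truth.extend(mine)
    return truth


def _draw_de_novo(
    child: str,
    model: GenomeModel,
    design: TrioDesign,
    rng: np.random.Generator,
) -> list[TruthDeletion]:
    events: list[TruthDeletion] = []
    # hotspot-restricted events, uniform per bp of hotspot sequence
    hs_mb = model.hotspot_length / MB
    n_hs = int(rng.poisson(design.de_novo_rate_per_mb * hs_mb)) if hs_mb else 0
    if n_hs:
        lengths = np.array([h.length for h in model.hotspots], dtype=float)
        p = lengths / lengths.sum()
        for _ in range(n_hs):
            hs = model.hotspots[int(rng.choice(len(model.hotspots), p=p))]
            mid = int(rng.integers(hs.start, hs.end))
            origin = (
                "de_novo_maternal"
                if rng.random() < design.maternal_fraction
                else "de_novo_paternal"
            )
            events.append(
                _place_deletion(child, hs.chrom, mid, True, model, design, rng, origin)
            )
    # optional genome-wide background de novo events
    if design.de_novo_genome_wide_rate_per_mb > 0:
        g_mb = model.genome_length / MB
        n_bg = int(rng.poisson(design.de_novo_genome_wide_rate_per_mb * g_mb))
        lengths = np.array([l for _, l in model.autosomes], dtype=float)
        p = lengths / lengths.sum()
        for _ in range(n_bg):
            idx = int(rng.choice(len(model.autosomes), p=p))
            chrom, clen = model.autosomes[idx]
            mid = int(rng.integers(0, clen))
            in_hs = model.hotspot_at(chrom, mid) is not None
            origin = (
                "de_novo_maternal"
                if rng.random() < design.maternal_fraction
                else "de_novo_paternal"
            )
            events.append(
                _place_deletion(child, chrom, mid, in_hs, model, design, rng, origin)
            )
    return events


def transmit_to_offspring(
    founder_truth: list[TruthDeletion],
    trios: list[Trio],
    design: TrioDesign,
    model: GenomeModel,
    seed: int | np.random.Generator = 0,
) -> list[TruthDeletion]:
    """Transmit parental deletions Mendelian-ly and add de novo events.

    Each parental deletion is transmitted independently with probability 1/2
    (the parental record's ``transmitted`` flag is set in place).  De novo
    deletions are added to each child at the design's hotspot rate (plus the
    optional genome-wide rate), maternal with probability
    ``maternal_fraction``.  Returns the offspring truth records.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    by_sample: dict[str, list[TruthDeletion]] = {}
    for d in founder_truth:
        by_sample.setdefault(d.sample, []).append(d)
    offspring: list[TruthDeletion] = []
    for trio in trios:
        for parent in (trio.father, trio.mother):
            for d in by_sample.get(parent, []):
                d.transmitted = bool(rng.random() < 0.5)
                if d.transmitted:
                    offspring.append(
                        TruthDeletion(
                            sample=trio.child,
                            chrom=d.chrom,
                            start=d.start,
                            end=d.end,
                            origin="founder",
                        )
                    )
        offspring.extend(_draw_de_novo(trio.child, model, design, rng))
    return offspring


def render_logr(
    truth: list[TruthDeletion],
    model: GenomeModel,
    samples: list[str],
    noise: NoiseModel = NoiseModel(),
    seed: int | np.random.Generator = 0,
) -> dict[str, IntensityTrack]:
    """Render per-sample LogR tracks on the model's SNP lattice.

    Copy-number-2 SNPs draw from N(0, sd_normal); SNPs inside one of the
    sample's heterozygous deletions draw from
    N(mu_deleted + delta, sd_deleted) where ``delta ~ N(0, sd_shift)`` is
    one draw per (deletion, sample) — see :class:`NoiseModel`.  Deletions
    covering fewer than 3 SNPs are rendered like any other — whether they
    are callable is the caller's concern, not the generator's.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    smap = model.snp_map
    by_sample: dict[str, list[TruthDeletion]] = {s: [] for s in samples}
    for d in truth:
        if d.chrom not in model.chrom_lengths:
            raise ValueError(f"truth deletion on unknown chromosome {d.chrom}")
        if d.sample in by_sample:
            by_sample[d.sample].append(d)
    tracks: dict[str, IntensityTrack] = {}
    for sample in samples:
        values = rng.normal(0.0, noise.sd_normal, size=smap.n_snps)
        for d in by_sample[sample]:
            lo, hi = smap.snps_in(d.chrom, d.start, d.end)
            if hi > lo:
                shift = rng.normal(0.0, noise.sd_shift)
                values[lo:hi] = rng.normal(
                    noise.mu_deleted + shift, noise.sd_deleted, hi - lo
                )
        tracks[sample] = IntensityTrack(sample=sample, values=values)
    return tracks


def simulate_cohort(
    seed: int,
    model: GenomeModel | None = None,
    design: TrioDesign | None = None,
    noise: NoiseModel | None = None,
) -> Cohort:
    """End-to-end cohort simulation from one master seed.

    Stage seeds (genome jitter, founder events, transmission, rendering)
    are spawned deterministically from the master seed.
    """
    design = design or TrioDesign()
    noise = noise or NoiseModel()
    ss = np.random.SeedSequence(seed)
    s_genome, s_events, s_transmit, s_render = ss.spawn(4)
    if model is None:
        from .genome import default_autosomes, default_genes, default_hotspots, build_genome_model

        model = build_genome_model(
            default_autosomes(),
            hotspots=default_hotspots(),
            genes=default_genes(),
            seed=np.random.default_rng(s_genome),
        )
    trios = [
        Trio(
            family=f"fam{i:04d}",
            child=f"fam{i:04d}-c",
            father=f"fam{i:04d}-f",
            mother=f"fam{i:04d}-m",
        )
        for i in range(design.n_trios)
    ]
    founders = [t.father for t in trios] + [t.mother for t in trios]
    founder_order = [
        f"fam{i:04d}-{role}" for i in range(design.n_trios) for role in ("f", "m")
    ]
    founder_truth = simulate_deletion_events(
        model, design, np.random.default_rng(s_events), founders=founder_order
    )
    offspring_truth = transmit_to_offspring(
        founder_truth, trios, design, model, np.random.default_rng(s_transmit)
    )
    truth = founder_truth + offspring_truth
    samples = founder_order + [t.child for t in trios]
    tracks = render_logr(
        truth, model, samples, noise, np.random.default_rng(s_render)
    )
    return Cohort(
        model=model,
        design=design,
        noise=noise,
        trios=trios,
        truth=truth,
        tracks=tracks,
    )
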