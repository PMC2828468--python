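# Methods

This note documents the models and numerical choices behind `delhot`: what
the synthetic trio-cohort generator emulates, how the rule-based caller and
the two-round verification are calibrated, what the hotspot scan and rate
calculators compute, and what passing tests do and do not establish.

## 1. The synthetic cohort generator

The generator produces father–mother–child trios of SNP-array LogR tracks
with a known deletion truth set. It emulates the *structure* a trio-based
rare-deletion analysis relies on, not any particular real dataset.

### Genome and SNP lattice

The default genome is a desk-scale mini-genome: 4 autosomes of 30 Mb
(120 Mb total) rather than 22 real autosomes. All downstream statistics are
length-normalised (per bp or per 0.6 Mb bin), so genome size only sets the
background-to-hotspot ratio, and tests that need a genome-scale bin count
(e.g. the null scan over B = 4400 bins) build a 2.64 Gb genome on the fly.
SNPs are placed every `snp_spacing` = 10 kb (≈ Illumina 300k density scaled
to genome length) with uniform jitter of ±0.45·spacing, giving ~12,000 SNPs
on the mini-genome. Deletion calls are expressed as runs of SNP indices;
bp intervals are 0-based half-open everywhere in memory (intensity files
store 1-based positions, converted on read/write).

### Hotspots

Thirteen hotspot intervals of 0.4–0.6 Mb covering exactly 7.0 Mb, with rate
multipliers {100, 100, 60, 60, 50 × 3, 40 × 3, 30 × 3} — a length-weighted
mean of ~54 with two extreme regions at 100× — mirroring a study design of
~13 regions, ~7 Mb, ~50-fold average enrichment and >100-fold extremes.

### Founder deletions

Founder deletion sites follow an inhomogeneous Poisson process: background
rate `founder_rate_per_bp` (default 2.4 × 10⁻⁹/bp), multiplied inside
hotspots. The default yields ~1.1 deletions per founder genome, i.e. ~0.9
deletions spanning ≥ 3 SNPs per transmitted genome — chosen once so that a
440-trio cohort carries a few hundred verifiable transmissions, the regime
the bookkeeping is meant for (no underlying per-founder count is published
for the real data; this is a reconstruction). Overlapping deletions within
one founder are re-drawn: only heterozygous, locus-exclusive events are
modelled.

Lengths are lognormal, truncated to [3 kb, 2 Mb] (array resolution bound on
one side, sub-chromosomal sanity on the other):

* hotspot deletions: median 54 kb, log-sd 1.15 — chosen so ~68% of lengths
  fall in 20–200 kb; the implied mean (~100 kb before truncation) sits near
  the reference value of ~94 kb;
* background deletions: median 27 kb (half the hotspot median), log-sd 1.40
  — a heavier tail, putting ~50% of lengths in 20–200 kb.

### Transmission and de novo events

Each parental deletion transmits independently with probability 1/2
(Mendelian segregation; the parental record's `transmitted` flag is set).
De novo deletions arise in offspring at `de_novo_rate_per_mb` per child per
hotspot-Mb, default 5/(440 · 7) ≈ 1.62 × 10⁻³, so a 440-trio cohort with
7 Mb of hotspots expects 5 events. They are restricted to hotspots by
default (an optional genome-wide rate, default 0, adds background de novo
events); position is length-uniform within hotspots, and origin is maternal
with probability 0.6 (modelling a 3-of-5 maternal parent-of-origin ratio).

### LogR emission and the per-genome detection coin

Copy-number-2 SNPs draw N(0, σ_normal) with σ_normal = 0.15. A deleted
segment draws one per-(deletion, sample) shift δ ~ N(0, σ_shift) with
σ_shift = 0.12, and each deleted SNP then draws
N(μ_del + δ, σ_del) with μ_del = −0.66, σ_del = 0.02.

The shared shift is the load-bearing choice. With purely independent
per-SNP noise, the probability of a ≥ 3-SNP run below a threshold rises
steeply with the number of SNPs spanned, so detection would depend strongly
on deletion length; long deletions would also fragment into several calls.
Real array failure modes are dominated by sample- and region-level effects
(DNA quality, intensity waves), under which a whole segment is either
cleanly displaced or not. Modelling that with a per-segment shift makes
strict-caller detection an approximately length-independent Bernoulli coin
per carrier genome, independent between parent and child for the same event
— exactly the regime in which the combined two-generation sensitivity is
S = 1 − (1 − s)². The stylisation is acknowledged: within-segment scatter
(σ_del = 0.02) is smaller than on real arrays, because its only role here
is to keep boundaries crisp while the shift carries the detectability
variance.

All randomness flows from one master seed through
`numpy.random.SeedSequence.spawn` (genome jitter, founder events,
transmission, rendering), so identical seeds give byte-identical cohorts.

## 2. The caller and its calibration

A deletion call is a maximal run of ≥ `min_run` = 3 consecutive SNPs with
LogR below the strict threshold. "Consecutive" means adjacent on the array;
runs are never merged across gaps; 2-SNP runs qualify only under relaxed
re-scan settings and carry provenance `rescued`. Samples with more than 20
calls are excluded ("more than" read strictly: 21 excludes, 20 does not),
and any exclusion removes the whole trio from verification.

The strict threshold default is **−0.575**, calibrated by Monte Carlo
(6,000 founder genomes, ~4,900 eligible events) so that the per-genome
sensitivity on truth deletions spanning ≥ 3 SNPs is 0.75 — the standalone
sensitivity the verification arithmetic assumes. At that cutoff false calls
on deletion-free genomes are ≪ 0.05 per genome (none observed in 933 clean
genomes). The relaxed re-scan threshold is **−0.30** (2 σ_normal): deep
enough that ~2-SNP noise runs almost never rescue (< 1% per scan window),
shallow enough that a true carrier segment — whose shift would have to
exceed +0.36 to escape — is confirmed in ≈ 98–99% of re-scans. The re-scan
region is the triggering call padded by 1 SNP.

## 3. Two-round verification and the ledger

Round 1 labels each affirmed offspring call: *transmitted* if a parental
call matches at tolerance 0 (exact first and last SNP), else if a relaxed
re-scan of either parent at the locus succeeds (transmitted, rescued), else
*de novo* — requiring a failed rescue in **both** parents. Round 2 walks
each affirmed parental call: an overlapping affirmed offspring call means
the transmission was already counted (overlap, not exact match, is used
here deliberately — with boundary noise an exact-match rule would re-count
round-1 events); otherwise the offspring is re-scanned, a success adds a
recovered transmitted deletion (flagged when the identical event was
already known from another trio), and a failure records a non-transmitted
parental chromosome. A deletion present in both parents is two candidate
transmissions, matching per-chromosome counting.

The ledger holds every count with two structural invariants enforced on
construction: `transmitted_total = matched + rescued (round 1)` and
`offspring_total_final = transmitted_total + de_novo + recovered (round 2)`.

Sensitivity is estimated from a pooled cross-tab: of all events known to be
present in a genome (transmitted ⇒ present in the carrier parent; verified
round-2 transmissions ⇒ present in the child), the fraction the strict
caller called in that genome. The combined sensitivity is S = 1 − (1 − s)²,
and true counts are `detected / sensitivity`, reported at full precision
and rounded to the nearest 10 for presentation. A ledger-based variant of
the estimator uses boundary-matched counts as a proxy for strict detection;
it is an approximation whenever boundary precision is imperfect.

## 4. Independence, rarity, and the hotspot scan

Calls collapse into independent events by transitive closure of boundary
matching (tolerance 0 by default: identical first and last SNP). Rarity
keeps events with ≤ 2 carriers in every single cohort — an absolute count,
not a frequency, since the reference cohorts (440–640 individuals) all used
"1 or 2 per ~500"; recurrence across cohorts never drops an event.

The scan tiles each chromosome from position 0 into fixed 0.6 Mb bins (the
final partial bin is kept and flagged) and assigns each event to exactly
one bin by midpoint. Expected bins with exactly k events under unbiased
placement are `B·Poisson(k; N/B)`; bins with ≥ 3 independent events are
hotspots, adjacent qualifying bins merge, and region limits are reported as
the min start / max end of member events (the raw bin extent is kept
alongside and used for densities, so short regions are not inflated).
Per-region p-values are per-bin Poisson upper tails; no multiple-testing
correction is applied when calling (the argument is from expected counts),
but a Bonferroni column is emitted for reference. Enrichment fold is the
per-bp event density inside a region divided by the density over the genome
excluding all hotspot regions, averaged with region-length weights.

## 5. Rates, lengths, exons

* De novo rate: `r = d/(2n) · (u/L)` per generation per chromosome per
  unit `u` (default 0.6 Mb); linear in `d` and `u`; presented to one
  significant figure with full precision retained.
* Disease-hotspot projection: `incidence × f_de_novo × f_deletion ×
  f_hotspot`, doubled for intron-only deletions that never ascertain
  clinically (`intronic_multiplier` = 2, per 0.7 Mb by default).
* Rate ratios are unit-normalised: `(r₁/u₁)/(r₂/u₂)`.
* Length statistics report mean, median, SD and the fraction of lengths in
  20–200 kb per group, with a 2×2 chi-square on in-range counts. The
  primary statistic is uncorrected (the reference analysis' test variant is
  unstated); the Yates-corrected variant is emitted alongside.
* An event is coding-affected iff its half-open interval intersects at
  least one annotated exon interval (UTRs are not distinguished; fixture
  gene models carry exons only). Gene models read from GFF3 (via gffutils)
  or BED12.

## 6. Problem sizes and test design

The default study condition is one 440-trio cohort on the mini-genome
(~1,320 tracks × 12,000 SNPs); simulation plus full analysis takes about a
second. Stochastic properties aggregate over replicate cohorts or seeds:
recovery and de novo purity over 6 × 440 trios (> 2,000 transmitted
events), the null scan over 50 seeds of a 4,400-bin genome, enrichment
recovery over 1,500 founders at a uniform 50× multiplier, and the de novo
rate over 50 replicate 440-trio transmissions. Statistical assertions use
3–3.5 SE bands around the analytic expectation so that seed-level noise
does not flip them; seeds are fixed.

## 7. Known limitations

* No B-allele frequencies, duplications (CN > 2), homozygous deletions,
  genotype calls, X chromosome, mosaicism, or linkage-disequilibrium
  structure; de novo parent-of-origin comes from simulation truth, not from
  phasing.
* The emission model's within-segment scatter is deliberately small (see
  §1); the generator does not reproduce wave artifacts, GC effects, or the
  HMM behaviour of production CNV callers, so passing tests demonstrate the
  bookkeeping and estimators, not performance on real intensity data.
* Founder deletions are drawn independently per founder, so recurrent
  identical events across unrelated carriers essentially never arise in
  simulation; carrier-collapse and rarity filtering are therefore exercised
  mainly by constructed fixtures.
* The rarity filter is applied to verified calls before scanning; orderings
  interleaving rarity with verification would change intermediate ledger
  counts but not the scan's inputs.
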