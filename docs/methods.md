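# Methods

This note records the models, conventions and design choices behind
`cghsig`, in the spirit of the methods documentation of mature analysis
packages: what is computed, under which assumptions, with which defaults,
and what the simulation-based validation does and does not show.

## Ratio model and scale

All analysis happens on the simple fluorescence ratio scale
(FR = test/reference), not log ratios. A test genome with `c` extra
copies (negative for loss) in a clonal fraction `f` of cells, hybridised
against a diploid reference, has expected ratio

    E[FR] = (2 + c·f) / 2 ,

so a heterozygous loss at full clonality gives 0.5, a homozygous loss
gives 0, and subclonality attenuates the deviation linearly toward 1.
Independent events on the same sample compose additively in `c·f` space
before conversion to a ratio. Noise is additive Gaussian on the ratio
scale with a per-sample SD; negative ratios are clipped to 0 (FR is
physically non-negative) and counted.

Sex chromosomes are measured against sex-mixed pooled reference DNA
(X dosage 1.5, Y dosage 0.5 in the pool), which makes their ratios
systematically off-diploid regardless of aberration status. The analysis
pipeline therefore removes sex-chromosome probes before any statistics;
the simulator still generates them so that the removal step is exercised.

## Robust per-sample noise (sigma clipping)

Each hybridisation gets its own scale estimate: starting from all
non-missing probe ratios of a sample, iterate

1. `center = median(retained)`, `sd = SD(retained, ddof=1)`,
2. reject retained points with `|x − center| > k_reject·sd`
   (`k_reject = 3`),

until the retained set stops changing, `|Δsd| < 1e-6`, or 50 iterations.
Aberrant probes (a few percent of the genome even in heavily rearranged
samples) are far outside 3 SD and are excluded after one or two rounds.
The retained-set SD is reported without a truncation correction, which
preserves the invariant `robust_sd ≤ plain SD`; the cost is a known ~1.5%
downward bias on clean Gaussian data (the fixed point of a ±3σ clip).
Consequences: calls made at `k·robust_sd` are very slightly anti-
conservative (an effective threshold of ~3.95 SD instead of 4), and
calibration checks of the false-call rate against `2·Φ(−k)` are run with
the generating SD, isolating threshold semantics from estimator bias.
Degenerate samples (all values identical) return SD 0 with a warning and
produce no calls.

## Calling and the recurrence screen

Ternary calls per probe and sample: +1 if `FR > center + k·sd`, −1 if
`FR < center − k·sd`, else 0; missing cells are never calls. Calls are
centred on the per-sample robust center rather than 1.0 exactly, which
absorbs small normalisation offsets. Two thresholds are used by
convention: k = 4 for the genome-wide aberration screen and k = 3 for
per-region call displays and signature flags. A per-sample (not cohort-
global) SD is the default because the per-sample SDs are the quantity the
noise model defines; a global value can be supplied to `call_matrix`
directly.

The preliminary screen requires, within a sample, a run of at least
`min_adjacent = 2` genome-adjacent probes called in the same direction
(runs never span chromosome boundaries; missing cells break runs), and
recurrence of the same adjacent probe pair, same direction, in at least
`min_samples = 3` samples of the cohort. Qualifying pairs are merged into
maximal loci for reporting; per-pair support counts remain available.
Requiring the same direction in both probes and across supporting samples
discards mixed-sign adjacent outliers, which are noise. Loci whose bp
footprint overlaps (≥ 1 bp) a merged CNV-mask interval are removed —
germline copy-number polymorphism is not evidence of somatic aberration.
All genomic intervals are 0-based half-open everywhere.

## Two-class SAM

The relative difference for probe *i* between classes 1 and 2 is

    d_i = (x̄_2i − x̄_1i) / (s_i + s0)
    s_i = sqrt[ (1/n1 + 1/n2) · (Σ_1 (x−x̄_1)² + Σ_2 (x−x̄_2)²) / (n1+n2−2) ]

with missing cells excluded per probe (class sizes recomputed); probes
with fewer than two values in either class are flagged and excluded from
ranking. The fudge factor `s0` is chosen by the percentile-CV rule:
candidates are the 0th–100th percentiles of `s` in steps of 5; for each,
probes are split into 100 equal-rank windows of `s`, the scaled MAD of
`d` is computed per window, and the candidate minimising the coefficient
of variation of those MADs wins (smallest percentile on ties; if all `s`
are identical every candidate coincides and that common value is
returned). A fixed `s0` can be supplied instead.

The null is obtained by permuting class labels: all C(n, n2)
arrangements when that count is ≤ 10,000 (classes kept distinct, so a
full class swap is a different arrangement), otherwise B = 1000
arrangements sampled uniformly with the run seed. For each arrangement
the full d vector is computed (same `s0`) and sorted; the expected
relative difference at rank r, `d̄_E(r)`, is the mean of the r-th order
statistic over arrangements, and each probe's **gap** is `d − d̄_E` at
its own rank.

For a threshold delta, the asymmetric cutpoints are: `cut_up` = the
smallest observed d among ranks whose gap exceeds +delta, `cut_low` = the
largest observed d among ranks whose gap falls below −delta; probes with
`d ≥ cut_up` or `d ≤ cut_low` are called. The estimated number of false
calls is the number of permuted d values beyond the same cutpoints,
aggregated over arrangements; FDR = false/called, capped at 1 (rows with
0 called report FDR 0 and are flagged by the called count).

**False-count aggregation.** The default aggregator is the **mean** over
permutations; `median` (the classical convention) and `q90` are
available. The mean is the default because of how the "largest set at
FDR = 0" selection rule behaves at the extremes: under the median, a
delta at which a single probe is called reaches FDR = 0 whenever the
observed extreme d beats the median of the permuted extremes — an event
of probability ≈ 1/2 under a pure-noise null, for any number of
permutations, making "FDR = 0" nearly meaningless. Under the mean,
FDR = 0 requires the cutpoints to beat *every* permutation, so the null
rate of non-empty FDR = 0 selections is ≈ 2/(B+1). No correction for the
proportion of true nulls (π0) is applied.

Two selections are provided, matching two distinct uses: the called set
at the smallest delta whose estimated FDR is 0 (the largest FDR-0 set),
and the top-k probes ranked by |gap| (ties by |d|, then genome order) —
the "enhanced delta" shortlist, default k = 22.

## Clustering and region signatures

Samples are clustered on the selected probe subset with average-linkage
agglomerative clustering on Euclidean distance (scipy implementation);
missing cells are imputed with probe-wise medians (logged). The merge
tree serialises to Newick with ultrametric branch lengths (differences of
merge heights); the 2-cluster cut is the quantitative readout for
class separation.

Region-level calls use a named region table (IGH, TCRA/D, TCRG, IKZF1 as
*primary*; the broad 7p and 9p segments as *secondary*). A sample is
flagged `deleted` for a region when ≥ `min_fraction = 0.5` of the
region's probes carry call −1 at ±3 SD, `no_data` when all region probes
are missing. With fully deleted planted regions the flags are insensitive
to the exact fraction, which is why 0.5 is safe as a default and exposed
as a parameter. `concomitant_7p9p` is true iff every secondary region is
deleted — monotone in deletions by construction. Cohort summaries report
per-region deleted counts and fractions over a designated class set
(default the lymphoid pair BCL + BCmix). Both the "9p13-24.1" and the
narrower "9p21-24" notions of the 9p region can be expressed in the
region table; the shipped default uses the broad segment.

## The synthetic cohort generator

The generator's defaults are the study conditions the analysis is
validated under; they are fixed, not tuning knobs.

* **Cohorts.** The full-scale configuration emulates a 105,000-probe
  24-chromosome array and a 92-sample cohort (78 CML + 14 controls). The
  two-class analysis cohort (`demo_config`, used by the bundled demo, the
  test suite and the acceptance script) is the 74-sample design — 12
  lymphoid (10 BCL + 2 BCmix) vs 62 others (31 CP + 2 AP + 15 BCM + 14
  controls) — at 10,000 probes on an 8-chromosome ~1.06 Gb genome, chosen
  so that every analysis completes at desk scale while each signature
  region carries the same probe multiplicity (IGH ~5, TCRG ~5, TCRA/D
  ~3-4, IKZF1 ~3, the 7p/9p segments tens to hundreds) as its full-scale
  counterpart.
* **Noise.** Per-sample SD drawn uniformly from (0.057, 0.187) —
  the observed range for arrays of this type — constant across probes,
  independent between probes; probe-to-probe autocorrelation, GC waves,
  dye bias and spatial artifacts are not modelled. Dye-swap replicates
  are not simulated: the FR matrix represents the already-merged ratio,
  and the SD range describes post-merge noise.
* **Signature events.** Primary regions are planted in every lymphoid
  sample; secondary regions in a shared subset of 7 (the same subset for
  all secondary regions, emulating joint segmental loss). Clonal fraction
  is drawn per sample-event from U(0.8, 1.0) — dominant clones. Planted
  deletions default to copy change −2 (biallelic). This is both the
  biology of the signature loci — V(D)J-recombination-driven deletions at
  IGH/TCR affect the rearranged alleles, and the hallmark loci show
  complete loss — and a detectability requirement: with noise SD up to
  0.187, a heterozygous deletion shifts the ratio by at most 0.5 < 3 SD,
  so ±3 SD region calls on −1 events are physically unrecoverable in the
  noisiest samples, whereas −2 events (shift ≥ 0.8) clear the threshold
  across the whole noise range.
* **CNV loci.** Polymorphic loci (including IGH-flanking ones) are
  assigned to samples of *all* classes by independent Bernoulli draws at
  the configured population frequency, at full clonal fraction (germline).
  The CNV mask written alongside the cohort contains exactly these loci.
* **Determinism.** Identical (config, seed) produces byte-identical
  on-disk artifacts; the truth set records every event, per-sample class,
  sex and noise SD.

What passing the simulation-based checks shows: the statistics are
implemented correctly (oracle equivalence), error control holds under the
modelled null, and the planted signature is recovered end to end at the
modelled effect sizes. What it does not show: robustness to correlated
noise, wave artifacts, normalisation failures, or clonal fractions far
below 0.8 — real-data properties outside the generator's scope.

## Paired-reference mode

Re-referencing a blast-crisis column against the patient's chronic-phase
column is modelled as per-probe division `FR_BC / FR_CP` (missing
propagates; zero CP ratios become missing). Under the noiseless model
this equals a physical BC-vs-CP co-hybridisation: shared aberrations
cancel toward 1 and BC-specific losses remain. With noise the two
channels' errors compound, and CP-only aberrations appear as reciprocal
artifacts (a CP-only 0.5 loss shows as ~2) — both documented behaviours,
not corrected.

## Validation scales

The test suite and `scripts/acceptance.py` run: 20 planted and 20 (10 in
the script) null cohorts at the demo scale with B = 1000 permutations;
oracle-equivalence checks on 200-probe × 20-sample instances (100 random
cases); a 1.5·10⁶-cell false-call-rate calibration; and exhaustive-vs-
sampled permutation comparisons at n = 8 (70 arrangements). These sizes
are the package's validation design; all randomness is seed-derived.

## Known limitations

* No segmentation (CBS/HMM), LOH inference, or GC correction; the
  adjacency screen is deliberately simple.
* The sigma-clipped SD's ~1.5% truncation bias is uncorrected (see above).
* FDR estimates come from the permutation plug-in without π0; with few
  distinct arrangements the FDR grid is coarse.
* Region flags use probe counts, not bp coverage; a region represented by
  a single probe degenerates to that probe's call.
* The simulator's uniform noise-SD law reproduces the observed *range*,
  not the full shape of the empirical SD distribution (its median, ~0.12,
  sits above the ~0.09 seen in practice where most samples are quiet).
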