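# Methods

## The model in brief

Two chromatin architectural proteins compete for nucleosome linker DNA: the
linker histone H1, associated with compacted, transcriptionally silent
chromatin, and the HMG protein HMGD1, associated with open, active
chromatin. The package treats three midpoint tracks — HMGD1-ChIP, H1-ChIP
and a total-nucleosome control — as the primary data and asks three
questions: where is each protein enriched, how does the balance
log2(HMGD1/H1) relate to transcription and chromatin openness, and does
that balance track the local nucleosome repeat length (NRL).

## Midpoint inference

**Single-end.** For each library we build per-base 5′-end depth vectors for
the forward and reverse strands and score every lag d in [0, 400] by the
Pearson correlation of forward depth at x with reverse depth at x + d,
pooling chromosomes by concatenating the aligned pairs. The lag profile is
a bump whose width is set by the fragment-length spread (sd ≈ 23 bp × √2),
so its raw argmax jitters by several bp at 10^5 reads; the profile is
therefore smoothed with a Gaussian (sd 8 bp, `profile_smooth_sd`, 0
disables) before the argmax. The estimated fragment length is best_lag + 1
and reads are shifted inward by half of it. The literal alternative of
shifting by the *full* estimated length would overshoot the dyad by half a
fragment; the half-length shift is the geometrically consistent reading and
is what the implementation does.

**Paired-end.** Fragment lengths are filtered to the central 95% of the
empirical distribution. Quantiles use the nearest-rank convention on the
sorted lengths (index ⌈qn⌉ − 1), bounds are rounded outward, and boundary
lengths are kept; at the simulator's defaults (Normal(146, 23)) the bounds
come out at ≈[101, 191] bp. Midpoints are ⌊(start + end − 1)/2⌋ — an
even-length fragment rounds down, a deterministic documented tie-break.

Per-read single-end midpoints are intrinsically noisy: the error carries a
±(L/2 − shift) term with sd ≈ 11.5 bp at the default fragment spread.
Because the sign of that term flips with strand, averaging the inferred
midpoints of the ~20 reads covering one nucleosome cancels it, leaving a
per-nucleosome RMS of ≈2.7 bp; accuracy statements in the tests and the
acceptance script are therefore per-nucleosome, while paired-end per-read
RMS (≈3 bp) directly reflects the simulated MNase trimming blur.

## Occupancy and association statistics

Expression is pseudocounted RPKM, log2-transformed, and split into tertiles
by rank (ties broken by gene id; remainders go to the low then medium
group). Feature classes use precedence promoter > exon > intron >
intergenic with promoters defined as ±1 kb of a TSS and resolved to the
nearest TSS. Densities are read fractions divided by length fractions, so
a uniform track scores 1 everywhere.

Promoter rates are log2((ChIP + ψ)/(total + ψ)) with ψ = 1 in every log
ratio throughout the package; the pseudocount guarantees finite values at
empty windows and is exposed as a parameter. The fixed windows are
−100..+500 bp (HMGD1) and −550..+50 bp (H1), strand-oriented. The
per-segment analysis uses eight configurable windows (an NDR window, four
downstream and three upstream nucleosome-sized windows, boundaries in
`occupancy.DEFAULT_SEGMENTS`); these boundaries are package defaults chosen
to match typical positioned-nucleosome geometry, not measured values.

Correlation confidence intervals use the Fisher transform with the normal
critical value and an n − 3 denominator. The nested F-test compares the
two-predictor model to each univariate model with numerator df 1 and
denominator df n − 3; fits go through ordinary least squares
(statsmodels), a residual at rounding-noise level is reported as a perfect
fit (F = ∞, p = 0), and an added predictor that cannot reduce the SSE
yields F = 0.

DHS-distance statistics tile each chromosome into non-overlapping 1-kb
windows. The per-base distance to the nearest DHS is an exact 1-D distance
transform (0 inside a DHS); the window statistic is log2(mean distance + 1)
— the +1 keeps in-DHS windows finite, since the bare log of a zero mean is
undefined. Occupancy values are log2(mean midpoint depth + ψ). Windows
within 2 kb of a TSS can be excluded (boundary kept at exactly 2 kb).
Chromosomes with no DHS are dropped with a warning rather than assigned a
cross-chromosome distance.

Mark clustering takes 2-kb TSS windows, mean mark signal per window,
normalized occupancy log2((ChIP + ψ)/(total + ψ)), pairwise Pearson R
across windows, and agglomerative clustering with distance 1 − R. Average
linkage is used — the standard choice for correlation-distance heatmaps;
the metric itself does not determine a linkage. Constant experiments are
excluded with a warning because their correlation is undefined.

## Repeat-length estimation

Regions (default 2 kb wide — the analysis is also valid at 1 kb and the
width is a parameter) are scored by log2((HMGD1 + 1)/(H1 + 1)) midpoint
counts, empty regions are dropped, and rank quintiles are formed with
genomic-order tie-breaks. The phasogram counts ordered rightward midpoint
pairs of the *total* track at separations 1..1200 bp within a region
(stratification uses the ChIP ratio only; anchors and counted midpoints are
total-track, so ChIP depth differences between quintiles cannot distort the
spacing signal). Ordered rather than symmetric counting halves the work
without moving any peak.

Peaks are found on a Gaussian-smoothed histogram (sd 5 bp, truncated at
3 sd, reflective boundary so total mass is conserved) restricted to
[120 bp, max_distance − 3 sd]; 120 bp excludes the sub-nucleosomal shoulder
created by read pairs from the same nucleosome. Local maxima are kept
greedily by height with mutual distance ≥ 120 bp. The NRL is the OLS slope
of peak position on peak index 1..k, with intercept (a no-intercept variant
is exposed; with arithmetic-progression peaks both give the exact slope).
The gel-ladder estimator regresses band size on band number per digestion
time and extrapolates the per-time slopes to time 0; a single usable time
point is returned unextrapolated and flagged.

## The simulator

The generator produces what the analysis assumes, with recorded truth:

* **Arrays.** Renewal process per region: first dyad at start + U(0, NRL),
  spacings Normal(NRL, jitter sd 5 bp) truncated below at 148 bp (core
  particles cannot overlap). Empirical mean spacing converges to the
  configured NRL, which the tests exploit.
* **Labels.** Each nucleosome is HMGD1 with probability
  logistic(slope · z), z the standardized log expression of the nearest
  gene when within 1 kb of its TSS, else −1 (intergenic baseline); H1
  otherwise. Exactly one label per nucleosome encodes the competition
  hypothesis. This logistic form is a modeling convenience — a minimal
  monotone coupling — not a biological claim; slope and noise are exposed
  in `SimulationConfig`.
* **Reads.** Poisson(20) fragments per nucleosome; lengths Normal(146, 23)
  rounded and clipped to [50, 400] so the central 95% spans ≈[101, 191] bp;
  fragment midpoint = dyad + rounded Normal(0, 3) trimming noise; ChIP
  experiments sample only matching-label nucleosomes. Single-end mode emits
  one 36-bp end per fragment with equal strand probability.
* **Annotation.** Non-overlapping 1.5-kb genes with alternating strands and
  two exons, log2 expression Normal(2, 2), a 200-bp DHS on the TSS of each
  top-tertile gene, Poisson exon tag counts proportional to
  2^log-expression × exonic length, and ≥3 activating (+z) and ≥3
  repressive (−z) mark tracks with Normal(0, 0.5) noise.
* **Spacing studies** cycle regions through the configured NRL strata
  (default 174/177/180/184/187 bp) while the HMGD1 probability decreases
  across strata, so the shortest repeat length co-occurs with the highest
  ratio, and the ratio-quintile pipeline should recover the strata.
* **Ratio-coupled expression** (`simulate_rate_expression`) is a
  summary-level generator for the model-comparison property: a latent
  per-gene ratio r ~ N(0,1) splits into hmgd = r/2 + e and h1 = −r/2 + e′
  (e, e′ ~ N(0, 0.5)) with expression r + N(0, 0.5), making the ratio a
  strictly better predictor than either half in population.

What the simulator does *not* emulate: sequence content and MNase sequence
bias, mappability, duplicated reads, thermodynamic (barrier-driven)
nucleosome positioning, chromosome-scale heterochromatin domains, and
dosage compensation. Passing recovery tests therefore demonstrate that the
estimators are correct under the stated noise model, not that real
libraries satisfy that model.

## Problem sizes and determinism

Test and acceptance runs use 500 regions per stratum (≈5 Mb of simulated
chromatin, ≈5.5 × 10^5 fragments per track), a 1-Mb / 200-gene genome for
the gene-centric analyses, 10^5 fragments for the filter bounds, and 100
replicates of n = 2000 genes for the model-comparison property — sizes at
which every recovery target is met with margin while a full run stays in
the tens of seconds. All randomness flows from a single
`numpy.random.Generator`; a fixed `SimulationConfig` reproduces outputs
exactly, and `scripts/acceptance.py` derives all component seeds from its
`--seed` argument.

## Known limitations

* The strand-covariation estimator assumes both strands sample the same
  fragment population; merging libraries with different fragment-length
  distributions first will blur the lag profile (estimate offsets per
  library instead).
* Promoter-segment boundaries and the peak-calling parameters (smoothing
  sd, 120-bp separation) are fixed defaults; heavily phased or very short
  arrays may need different values.
* `nested_f_test` assumes the full model adds exactly one predictor
  (numerator df 1).
* The gel-ladder extrapolation is a straight line in digestion time, which
  is adequate only near the origin of the digestion series.
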