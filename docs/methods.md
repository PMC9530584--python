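# Methods

This note documents the statistical procedures, the synthetic-data model and
the numerical conventions the package commits to, including the choices made
where more than one defensible convention exists.

## The detrended fluctuation function

Given one patient's glucose series x(1..N) (mmol/L, nominal 5-minute grid),
the fluctuation value at window length l (in samples) is computed as:

1. integrate: y(t) = Σ_{i≤t} (x(i) − x̄), with x̄ the mean over the *whole
   recording* (multi-day recordings are one sequence, not per-day pieces);
2. partition y into m = ⌊N/l⌋ consecutive, non-overlapping, forward-only
   windows; the trailing remainder of fewer than l points is discarded;
3. remove an ordinary-least-squares line from each window (first-order
   detrending only);
4. F_d(l) = sqrt( (1/(m·l)) Σ residual² ) over the m·l retained points.

Conventions worth stating because DFA variants differ: there is no reverse
pass, no overlapping windows, no polynomial order above 1, and no log-spaced
thinning of l — profiles cover every integer l in the requested range
(default 2..130). l counts samples; a window of l = 100 five-minute samples
spans (100 − 1)·5 min = 8 h 15 min first-to-last. F_d carries the units of
the integrated series (mmol/L·sample); only relative comparisons across
patients are ever used, so the unit never matters downstream.

Degenerate inputs: constant series give F_d = 0; l < 2 or l > N raise. When
ingest has split a trace at sensor gaps (see below), each contiguous segment
is windowed separately — windows never span a gap — while the integration
mean stays global; squared residuals are pooled across segments before the
RMS, and scales longer than the longest segment are NaN (dropped pairwise in
cohort-level curves).

## Ingest rules

CGM exports are joined to the nominal 5-minute grid at read time. Gaps of at
most 15 minutes are filled by linear interpolation (the filled count is kept
on the trace); longer gaps split the trace into segments. Glucose outside
the plausible sensor range 2.2–22.2 mmol/L is flagged but retained — there
is no principled exclusion rule for sensor artifacts, so none is invented.
Timestamps are serialized as ISO-8601 UTC; internally everything is seconds
since trace start, avoiding timezone arithmetic entirely.

## Classical metrics

* SD uses the N−1 denominator; %CV = 100·SD/mean.
* TIR counts samples in [3.9, 10.0] mmol/L with both bounds inclusive, each
  sample equally weighted (the grid is uniform after ingest, so this equals
  time-weighting).
* MAGE: the trace is reduced to alternating turning points (plateaus and
  monotone runs merged, endpoints kept); excursions are absolute differences
  of consecutive turning points; those exceeding 1×SD of the whole trace are
  averaged, counting both ascending and descending excursions (the
  "MAGE-avg" convention). Published MAGE implementations disagree on the
  direction rule; the symmetric average is used because nothing in the
  analysis depends on excursion direction. Returns 0 when nothing qualifies.

## Scale selection

For each l, Spearman's rank correlation (average ranks on ties) is taken
between F_d(l) across patients and FCP, and separately 2-hour postprandial
C-peptide. l* maximizes |r| against FCP only — the postprandial curve is
reported, not optimized. Ties break toward the smaller l (more windows per
trace). Scales with fewer than 3 usable patients are dropped with a warning.
Being rank-based, the selection is invariant to monotone transforms of
C-peptide. No multiple-testing correction is applied across the ~129 highly
correlated scales: the procedure is model selection, not inference, and the
output metadata says so.

## Classification and validation

* Orientation: each marker is oriented so the positive class (LADA) sits on
  the high side — the orientation that makes the rank AUC ≥ 0.5, with class
  medians breaking an exact 0.5. The orientation is recorded in the report.
* AUC by the rank/pair method (ties count ½); 95% CI from the DeLong
  structural-components variance estimator.
* Operating point: Youden's J = sens + spec − 1, maximized over midpoints
  between adjacent distinct scores; J ties break toward higher specificity,
  then the higher cutoff. The rule is "predict LADA when the oriented score
  is ≥ cutoff"; reported cutoffs are on the raw marker scale.
* Cohen's kappa uses the marginal-product chance correction and raises when
  chance agreement is exactly 1.
* Cross-validation: stratified 10-fold (per-class fold sizes differ by ≤1).
  Within each repetition l* is re-selected and the cutoff re-fitted using
  training patients only; both are applied frozen to the held-out fold.
  Fold means are arithmetic; the 95% CI of a fold mean uses the
  t-distribution with k−1 degrees of freedom. With fewer than 10 patients in
  the smallest class the fold count degrades (with a warning) rather than
  failing; single-class test folds record missing test metrics.
* Cohort summary tables use Shapiro-Wilk (α = 0.05 in both groups) to choose
  between the two-sample t-test and the Mann-Whitney U test.

## The synthetic cohort generator

The generator emulates the structure the analysis assumes, not glucose
physiology. Per patient of class c ∈ {LADA-like, T2DM-like}:

* FCP ~ log-normal(median_c, log-sd_c); 2hCP = FCP × log-normal ratio.
* amplitude factor a = exp(−k·FCP), k = 0.35: the planted, strictly
  monotone inverse link between beta-cell function and glycemic
  variability.
* glucose g(t) = basal_i + meals + circadian + AR(1) noise, clipped to the
  sensor range 2.2–22.2 mmol/L, 288 samples/day:
  * basal_i ~ N(mean_glucose_c, mean_glucose_sd_c) — between-patient spread
    of mean glucose;
  * three Gaussian meal bumps/day (08:00, 12:30, 18:30; σ = 45 min), peak
    height meal_amp_base·a with ±20% log-normal meal-size jitter — the
    multi-hour excursion channel that carries the planted coupling cleanly;
  * a 0.3 mmol/L circadian sinusoid (minimum ≈ 04:00);
  * AR(1) noise, lag-1 coefficient 0.9, innovation sd
    noise_sd_base·a·h_i with h_i ~ log-normal(0, 0.35) — a per-patient
    nuisance multiplier for everything that moves glucose but has nothing to
    do with C-peptide (diet, activity, sensor noise). It dilutes the
    coupling at short window lengths, so scale selection has a real job:
    the correlation curve rises with l toward the meal-block scales, and l*
    lands in a stable multi-hour band across seeds.

Default calibration (chosen once, against the published two-class contrast,
and not revisited): FCP medians 0.31 / 1.82 ng/mL with log-sds 1.43 / 0.53
derived from the published IQRs; postprandial ratios 1.74 / 2.30; mean
glucose 9.41 ± 2.13 / 8.31 ± 1.42 mmol/L; meal_amp_base = 5.0 mmol/L and
noise_sd_base = 1.4 mmol/L from a variance budget targeting within-patient
glucose SD ≈ 3.3 (LADA-like) and ≈ 2.1 (T2DM-like): with a ≈ 0.90 / 0.53 at
the class FCP medians, the meal channel contributes ≈ 0.33·meal_amp·a and
the AR(1) channel ≈ 2.29·noise_sd·a of stationary sd, giving ≈ 3.3 / 2.0.
Insulin-treatment flags are drawn at the published class rates (93% / 33%)
but have no effect on the trace — treatment effects are deliberately not
modelled. Default cohort size 60/120 preserves the published 1:2 class
imbalance at a desk-scale n.

What the generator does **not** emulate — and therefore what passing tests
do not establish about real data: insulin-dose timing and treatment effects
on variability, sensor drift/calibration error, meal-size and meal-time
variation beyond amplitude jitter, hypoglycemia-counterregulation dynamics,
and the absolute magnitude of F_d (synthetic values at l ≈ 100 are an order
of magnitude larger than clinically reported ones because the AR(1) noise
has more low-frequency power than tightly regulated glucose; every
downstream statistic is rank- or threshold-based, so only orderings
matter). The pipeline's recovery results demonstrate internal validity of
the method, not clinical performance.

## Problem sizes and determinism

Analyses and tests run at the default cohort (180 patients × 2016 samples,
profiles over l = 2..130) — a full run takes a few seconds — and the
held-out-AUC summary repeats it over 10 independently seeded cohorts. A
single root seed fans out via `numpy.random.SeedSequence` into named
sub-seeds (generation, fold shuffling), so identical configurations produce
byte-identical artifacts, and reports echo the seed and a configuration
hash.

## Known limitations

* l* on synthetic cohorts varies within a band (roughly 50–100 at the
  default calibration) rather than pinning a single value; only the band is
  meaningful.
* The DeLong CI is asymptotic and degenerates to zero width under perfect
  separation.
* MAGE on a strictly monotone trace counts the single run as one excursion;
  with fewer than 3 samples it is undefined and raises.
* The Youden cutoff is unique only up to the gap between adjacent scores;
  the midpoint is reported.
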