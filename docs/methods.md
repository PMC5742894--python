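# Methods

## Secretion model

The diurnal melatonin concentration is modelled as

MLT(t) = b1 + b2·exp(−ln2·[(cos(π(t−b3)/12) − 1)/(cos(π·b4/24) − 1)]²),

a 24-h-periodic bell with baseline `b1` ≥ 0 pg/mL, amplitude `b2` > 0
pg/mL, acrophase `b3` (stored mod 24 into [0, 24) h) and FWHM `b4` ∈
(0, 24) h, interpreted as estimated sleep duration.  The parameterization
is uniquely determined by three properties locked in the test suite:
peak `b1 + b2` at `t = b3`, half maximum `b1 + b2/2` exactly at
`b3 ± b4/2`, and 24-h periodicity.  The exponential factor lies in
(0, 1], so the curve never drops below `b1` and no clipping is needed.
The single assumed waveform is unimodal and symmetric about the peak; no
multi-harmonic cosinor terms, light exposure, or two-process sleep
dynamics are modelled.

### DLMO markers

The 50%-relative-threshold markers are exact consequences of the FWHM:
`on50 = b3 − b4/2`, `off50 = b3 + b4/2` (mod 24).  The 25% markers use
the conventional linear half-width factor: `on25 = b3 − f·b4`,
`off25 = b3 + f·b4` with `f = 2/π` by default.  Two alternatives are
exposed because the convention is not universal:

* `f = 0.636945` (`EMPIRICAL_QUARTER_FACTOR`): the constant implied by
  the reference cohort's published 25% columns, which are consistent
  with a symmetric factor slightly above 2/π ≈ 0.636620 but match
  neither 2/π nor the exact crossing;
* `dlmo25_exact`: the true quarter-amplitude crossings, obtained in
  closed form from `cos(π(t−b3)/12) = 1 + √2(cos(π·b4/24) − 1)`.  For
  `b4` ≳ 15.26 h the curve never falls to `b1 + b2/4`; this is reported
  as an explicit "threshold unattained" result rather than an error.

Neither 25% option is silently preferred when validating against the
reference tables; only the factor-independent quantities (50% markers,
`b_max`, medians of printed columns) are asserted numerically.

## Curve fitting

Per-subject parameters are estimated by unweighted nonlinear least
squares (scipy's bounded trust-region-reflective solver, tolerances
1e−14) with box constraints `b1 ≥ 0`, `b2 > 0`, `b4 ∈ (0.5, 23.5)`.  The
`b4` bounds keep the FWHM normalisation away from its singularities at 0
and 24 h; no physiological sleep duration approaches either.  The start
point is deterministic — baseline = min sample, amplitude = range, phase
= time of the (earliest) maximum sample, FWHM = 8 h — and an optional
8-point multistart over 3-h phase offsets handles the one multimodal
axis.  Weighting is uniform because no heteroscedasticity model is
assumed; the noise enters the analysis later through the relative gamma
tolerance instead.

Fit quality is screened with three diagnostics: explained variance
100·(1 − SSR/SST) floored at 0 (gate: > 81%), Pearson R between observed
and fitted values (gate: > 0.90), and a Shapiro–Wilk p-value on the
residuals (reported, not gated).  A numerically perfect fit (residual
range below 1e−9 of the data scale) reports residual-normality p = 1,
since the residuals then carry no distributional signal.  Non-convergence
is a reported state (`converged=False` with best-effort parameters), not
an exception, so one refractory subject cannot abort a cohort run.

Each profile needs ≥ 5 samples (one more than the free parameters) with
times unique mod 24; a single 24-h cycle is assumed, so duplicate clock
times across days are rejected at input.

## Gamma shape statistic

Each measurement `(t_m, MLT_m)` is scored by
γ(t_m) = min over t of √[(t_m−t)²/δt² + (MLT_m−MLT(t))²/δMLT²] with
δt = 20 min and δMLT = 5% of the measured value.  Implementation
choices fixed for reproducibility and locked by a brute-force oracle
test:

* the time difference is circular mod 24, so samples near midnight are
  compared fairly with curve points on the other side of the wrap;
* δMLT uses `max(measurement, floor)` with floor 1 pg/mL, so zero-valued
  daytime samples keep a finite tolerance;
* the minimisation runs on a dense grid (0.25-min step) followed by
  bounded scalar refinement around the best grid point; the result is
  within 1e−4 of the fine-grid optimum (tested against an exhaustive
  0.1-min grid at 1e−3).

`max γ` over a profile's points classifies secretion: ≤ 2 bell-like,
> 2 disturbed.  The reference curve is always the subject's own fit.
Note a useful anchor: a measurement sitting exactly one concentration
tolerance above the peak (i.e. at `b_max/0.95`, a vertical offset of
exactly 5% of the measured value) scores γ = 1 by the standardisation
definition.

## Group statistics

Cohorts are compared per parameter (b1, b2, b3, b4, b_max, four DLMO
markers, max γ) with the two-sided Mann–Whitney U test: exact
enumeration p-value when `n_a·n_b ≤ 400` and the pooled sample is
tie-free, otherwise the normal approximation with midranks, tie
correction and continuity correction.  U is computed by rank summation
and satisfies `U(a,b) + U(b,a) = n_a·n_b`.  Kruskal–Wallis (tie-corrected
H, χ² p with k−1 df) covers more than two groups; the degenerate all-tied
case returns H = 0, p = 1 by convention.  A paired Wilcoxon signed-rank
test is provided but unused by the default pipeline, which compares
independent cohorts.  No multiple-testing correction is applied; reported
p-values are raw, flagged at the conventional 0.05 level.

Two reporting conventions deserve mention.  Published group tables for
this model truncate (not round) medians to two decimals; `truncate_2dp`
reproduces this, while machine outputs keep full precision.  Circular
quantities (phase, DLMO times) are rank-tested on their [0, 24)
representatives — the convention of the motivating analyses — which is
not circular-invariant near the midnight wrap; the limitation is
inherent to the convention, not to the implementation.

## Synthetic cohort generator

The generator emulates the study conditions the pipeline assumes:
3-hourly sampling at 0, 3, …, 21 h, bell or triangular ("tent")
waveforms, group-specific parameter priors, and multiplicative
measurement noise (independent mean-one log-normal factors, default
CV 10%, consistent with the relative 5% tolerance in the gamma
standardisation).

Priors are anchored at the published group medians (AG: b1 7.83, b2
167.46, b3 3.59, b4 8.05; CG: 6.16, 142.51, 1.38, 7.07; EG: 5.84,
116.34, 2.34, 7.32).  Dispersions are not published anywhere, so the
defaults are fixed a priori as follows and not revisited:

* AG scales from the reference cohort's own robust (MAD-based)
  dispersions: log-σ 0.6 for b1, 0.4 for b2, σ 1.1 h for b4;
* the AG phase prior is a shifted log-normal (1 h + log-normal with
  median 2.59 h, log-σ 0.65), i.e. right-skewed toward later clock
  times: the reference phases are strongly right-skewed (1.55–12.18 h
  around median 3.59), as expected for a delayed-sleep-phase population,
  and this skew—phase delays compensated by long sleep duration—is what
  makes the DLMO *onsets* statistically uninformative while the
  *offsets* separate the groups;
* control-like groups use symmetric wrapped-normal phases and tighter
  scales typical of healthy pediatric circadian markers (CG: σ(b3)
  1.0 h, σ(b4) 0.8 h; EG intermediate: 1.5 h, 1.0 h).

Tent waveforms share the bell's baseline, peak and FWHM (linear fall to
baseline over a full base width 2·b4, periodic mod 24), so ground truth
stays comparable across waveforms.  The tent fraction defaults to 6/9
for AG (the reference cohort's disturbed fraction) and sub-half values
for EG/CG.  Cohort generation is a pure function of the spec including
its seed; the number of tents is exactly `round(mix·n)` with seeded
placement.

### What the generator does and does not emulate

It reproduces the sampling design, the bell/triangle shape dichotomy,
median-anchored between-subject variability and relative measurement
noise.  It does not model assay detection limits, within-night
fluctuations, seizure or drug effects, age trends, or correlations
between parameters.  Synthetic significance patterns are therefore
qualitative mirrors of the published group differences (which parameters
separate the groups), not quantitative reproductions of their p-values.

## Validation design and problem sizes

* Derived-marker and median reproduction use the published nine-subject
  parameter table directly (exact, printed-precision tolerances: 1e−4 on
  four-decimal clock times; the published table's last digits are
  themselves truncations/roundings of values computed from rounded
  inputs).
* Curve and gamma minimisers are checked against dense-grid oracles on
  100 randomised parameter sets each.
* Parameter recovery runs 200 seeded noisy profiles (8 samples, 10% CV);
  median absolute errors are bounded at 0.5 h (phase) and 1.0 h (FWHM),
  with exact (1e−3) recovery demanded noiselessly.
* The exact Mann–Whitney p is compared with a full enumeration oracle
  for every group-size pair up to 6.
* The group significance pattern is judged on median p-values across 15
  replicate seeded 9-vs-40 cohort draws, which is robust to single-draw
  rank noise.

## Known limitations

* Tent/bell classification from 3-hourly samples is not fully
  identifiable: a narrow triangle whose samples happen to be
  interpolable by a bell scores γ ≈ 0 even noiselessly.  Tests
  accordingly assert strong stochastic separation and high (not perfect)
  detection rates — e.g. 89/100 low-noise tents flagged at the tested
  seed — mirroring the overlap visible in the reference cohort's own
  γ values, rather than a perfect dichotomy no method could deliver at
  this sampling density.
* At the default 10% noise even bell profiles often exceed max γ = 2
  (a 10% deviation is twice the 5% tolerance), so verdicts at that noise
  level describe total disturbance (shape + noise), not waveform alone.
* Each profile is fitted independently; no mixed-effects pooling across
  subjects.
* Exact Mann–Whitney enumeration is limited to small tie-free samples;
  midrank/normal approximation takes over beyond that.
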