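# Methods

## Problem and model

`tempagree` quantifies agreement between temperature monitoring devices
measured repeatedly on the same participants — the typical design of a
perioperative method-comparison study in which each participant is read by
several monitors at a few fixed time points (here 0/10/20/30 minutes after
spinal anaesthesia).

Classical Bland–Altman analysis summarises the paired differences
`d = y_A − y_B` by their mean (bias) and 95% limits of agreement
`bias ± 1.96·SD`. It assumes one independent difference per participant.
Applied naively to repeated measures it understates the uncertainty of the
bias and over-weights participants with more readings. `tempagree` instead
fits a variance-components model to the differences:

    d_ij = μ_d + b_i + ε_ij,
    b_i  ~ N(0, σ_b²)   (participant random intercept),
    ε_ij ~ N(0, σ_w²)   (residual),

estimated by restricted maximum likelihood (REML). The reported quantities
are:

- **bias** `μ_d` with a standard error that respects clustering,
  `Var(μ̂_d) = 1 / Σ_i n_i/(σ_w² + n_i σ_b²)`;
- **limits of agreement** `μ_d ± z·σ_total` with
  `σ_total = √(σ_b² + σ_w²)` and `z` the exact two-sided Normal quantile
  (1.959964… at the default 0.95 level, not the rounded 1.96): a 95%
  prediction interval for a single future difference on a new participant;
- **agreement probability at a clinical margin** m (default ±0.5 °C):
  `Φ((m − μ_d)/σ_total) − Φ((−m − μ_d)/σ_total)`, reported alongside the
  empirical fraction of observed differences within the margin (boundary
  inclusive), since the two answer subtly different questions;
- **empirical LOA coverage**: the fraction of observed differences inside
  the estimated limits, a conservativeness diagnostic;
- **Pearson correlation** of the raw paired readings, deliberately without
  any repeated-measures adjustment, with a non-parametric bootstrap CI that
  resamples whole participants so clustering is respected in the interval
  even though the point estimate ignores it.

### REML implementation

The one-way random-intercept model admits a profiled REML criterion in the
single variance ratio ρ = σ_b²/σ_w²: for fixed ρ the GLS mean and σ_w² are
closed-form, leaving a 1-D criterion

    (N−1)·log σ̂²(ρ) + Σ_i log(1 + n_i ρ) + log Σ_i w_i(ρ),
    w_i = n_i/(1 + n_i ρ),

minimised by bounded scalar optimisation over log ρ with the σ_b = 0
boundary checked explicitly. This is numerically equivalent to a general
mixed-model fit (the test suite cross-checks against statsmodels `MixedLM`
REML to ~1e−5) but runs in about a millisecond at n = 166 × 4, which makes
the unconditional parametric bootstrap (thousands of refits) cheap.
Boundary estimates σ_b = 0 are legitimate and returned as such.

Degenerate inputs fail loudly: a single participant, fewer than three
differences, or identical differences (σ_w would be 0) raise
`DegenerateDataError`. With exactly one difference per participant σ_b and
σ_w are not separately identified; the fit then collapses *exactly* to the
classical Bland–Altman estimate (sample mean ± z·sample SD, SE = SD/√n) and
is flagged `components_identified = False`, `method = "classical"`.

An optional `include_time_effect` fit adds fixed offsets per time point
(via statsmodels MixedLM) and reports the bias as the average of the
per-time means; the default keeps a constant device bias over time, with
the per-time-point sensitivity table as the check of that assumption.

### Bootstrap

LOA uncertainty comes from an **unconditional parametric bootstrap**: each
replicate simulates a complete dataset from the fitted model — fresh random
intercepts (not conditional on the estimated ones) and fresh residuals on
the observed participant/reading structure — refits, and recomputes bias,
halfwidth and both bounds; CIs are percentile quantiles (not BCa). 2000
replicates by default; a master seed is required for reproducibility, and
replicates whose refit fails are dropped and counted (a warning is recorded
if more than 5% drop). The correlation bootstrap resamples participants
with replacement, moving all of a participant's rows together; resamples
with zero variance in either device are likewise dropped and counted.

## Clinical metrics

The **error grid** classifies each complete reading pair by clinical
consequence with margin 0.5 °C and action thresholds <36.0 °C
(hypothermia) / >38.0 °C (hyperthermia):

- **green** — |a−b| ≤ 0.5 (inclusive), or both readings on the same
  actionable side (both < 36.0, or both > 38.0): same clinical
  interpretation;
- **yellow** — disagreement beyond the margin with neither reading
  actionable;
- **red** — the readings imply different actions: exactly one actionable
  (and the margin exceeded), or the two actionable in *opposite*
  directions. The opposite-directions case is not covered by the verbal
  rules the grid derives from; it is assigned red here because conflicting
  indicated actions are at least as significant as one indicated action the
  other monitor misses.

Boundary semantics follow the clinical definitions: "within 0.5" is
inclusive (≤), the action thresholds strict (< 36.0, > 38.0).

**Hypothermia detection** flags a participant if *any* reading by the
device inside the time window (default 0–30 min) is strictly below
36.0 °C, on the plausibility-filtered table. Participants without any
reading by that device in the window are excluded from the denominator and
counted separately — the alternative (keeping them as non-detections) would
conflate missingness with normothermia. Detection proportions carry exact
(Clopper–Pearson) binomial CIs by default; Wilson and Wald are selectable.

**Plausibility filter**: readings ≤ 34.0 °C are physiologically implausible
in this setting and removed (set missing) before the main analysis. The
boundary is inclusive and the operation idempotent; the unfiltered analysis
is available as the `include_implausible` sensitivity variant.

## Synthetic data generator

`SyntheticConfig`/`generate_table` emulate the statistical structure the
analysis assumes: a person-specific starting temperature
(N(36.6, 0.4²) °C), an average change at each time point
(0/−0.3/−0.5/−0.6 °C at 0/10/20/30 min — a gentle cooling trajectory that
yields a within-30-min hypothermia prevalence of order one half to two
thirds for the reference device), a device-specific bias (heat_flux 0
as reference, oral +0.5, infrared +0.4 °C), and independent Gaussian
measurement noise per device (0.6/0.5/0.7 °C), giving paired-difference
total SDs around 0.9–1.1 °C and hence 95% LOA of order ±2 °C. Corruption is
applied independently per reading: replacement by a uniform draw from
30.0–34.0 °C with probability 0.01 (exercising the ≤34 filter) and
missingness with probability 0.02.

Under this mechanism the participant baseline cancels exactly in a
same-person difference, which would force σ_b = 0 for every pair — unlike
real device comparisons, where differences cluster by participant. The
generator therefore adds an optional participant-by-device random intercept
(SD 0.3 °C by default), an extension beyond the minimal mechanism, giving
each pair a between-participant difference SD of `person_device_sd·√2`.
`true_pair_parameters` returns the closed-form (bias, between-SD,
within-SD) truth for any pair, used throughout the tests for parameter
recovery.

What the generator does **not** emulate: biophysical thermoregulation
(redistribution kinetics, warming-device effects), proportional bias
(device disagreement that varies with the underlying temperature — observed
in real comparisons as a slope in the Bland–Altman plot), non-Gaussian
heavy-tailed noise, and informative missingness. Passing tests therefore
demonstrate correctness of the estimators under the stated model, not that
any particular pair of real devices agrees.

## Numerical and design choices

- Differences, not raw readings, are the modelling target: the comparison
  table is organised by device pair, and the difference model needs no
  assumption about the shared physiological trajectory (it cancels). A raw
  readings model (participant intercept + device fixed effects) is
  implicitly available through the generator but is not the reporting path.
- Sign convention: first-named minus second-named device; swapping the
  order negates the bias and swaps/negates the LOA bounds (tested).
- REML rather than ML, so the variance components are unbiased to first
  order in the small-cluster setting (4 readings per participant).
- Report-layer rounding to one decimal; all computation in full float64.
- Problem sizes in the test suite (166 participants × 4 time points, 200
  recovery replicates, 100k-draw calibration checks, 500-replicate
  bootstraps in the repeated sanity checks, 2000 by default elsewhere) are
  the study-scale defaults of the package.

## Known limitations

- No proportional-bias (regression-based) limits of agreement: when the
  between-device difference depends on the underlying temperature, a single
  bias ± halfwidth understates disagreement at the extremes. The
  Bland–Altman plot with error-grid shading is the diagnostic for this.
- The agreement probability and LOA assume Gaussian components; heavy tails
  make the LOA anti-conservative.
- The error grid is the three-zone temperature grid only; no glucose-style
  (Clarke/Parkes) grids.
- Per-time-point analyses use the classical estimator within a slice and
  are only reported for slices with ≥ 3 complete pairs.
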