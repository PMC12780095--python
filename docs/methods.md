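# Methods

This note documents the models, fixed constants and numerical choices behind
`accelmort`, what the synthetic-data generator does and does not emulate, and
the design decisions taken where the problem was genuinely open.

## Signal stage

**Autocalibration.** Post-hoc estimation of per-axis gain and offset so that
still-period magnitudes equal 1 g. Still windows are non-overlapping 10 s
spans with per-axis SD below 13 mg. The fit is iteratively reweighted least
squares: each round projects the corrected still-window means onto the unit
sphere and regresses, per axis, the projected coordinate on the raw one;
windows far from the sphere are down-weighted. Iteration stops when the mean
absolute magnitude error improves by less than 1e-6 g (max 100 rounds). The
reported `calibration_error_g` — the quantity the > 0.01 g exclusion rule is
applied to — is the post-correction error; a configuration switch is the
natural place to change that, since conventions differ between pipelines.
Gain and offset are only separable when the still orientations span the
sphere, so the fit requires at least 10 still windows and an orientation
spread of ≥ 0.15 g on at least two axes; otherwise the recording passes
through uncorrected with the error evaluated on whatever windows exist.

**Non-wear.** Each 15-min block is judged on the surrounding 60-min window:
non-wear when at least 2 of 3 axes have window SD < 13 mg *and* window range
< 50 mg. These constants mirror the defaults of widely used wrist pipelines.
A consequence worth knowing: an isolated still period shorter than ~90 min
produces no flags at all, because every surrounding window overlaps moving
signal — the detector is deliberately tuned for sustained off-body periods,
not brief rests.

**Clipping.** An epoch is clipped when more than 50% of its samples on any
axis lie at ≥ 0.99 of the device's dynamic range (default ±8 g). Clipping
overrides wear. Both constants are exposed in the module configuration.

**Epoch grid.** Half-open 5 s windows anchored at recording start (not clock
midnight), with the trailing partial epoch discarded. The epoch length must
divide 86 400 s so that day boundaries downstream stay aligned. Keeping the
grid anchored to the recording keeps the signal stage timezone-free; calendar
alignment is handled entirely in the day-summary stage.

## Epoch measures

ENMO is the epoch mean of (vector magnitude − 1 g) with negatives truncated
to zero; MAD the epoch mean absolute deviation of the magnitude from its
epoch mean; both are reported in mg and are exactly rotation-invariant.

MIMS and Counts are filter chains with fixed constants, all collected in
`MIMS_CONSTANTS` / `COUNTS_CONSTANTS` and overridable per call:

* **MIMS**: per axis — linear-interpolation resampling to 100 Hz; cubic-spline
  continuation of range-saturated runs (samples at ≥ 0.95 of range), capped at
  1.5× range; band-pass 0.2–5 Hz Butterworth order 4 applied forward-backward
  (zero phase); rectification; trapezoidal integration per epoch; per-axis
  integrals below 1e-4 truncated to zero; axes summed.
* **Counts**: per axis — resampling to 30 Hz; a causal band-pass IIR
  (Butterworth order 4, 0.29–1.66 Hz, designed at 30 Hz) initialised at its
  steady state so a constant input produces no startup transient; decimation
  to 10 Hz; clipping at 2.13 g; rectification; dead-band below 0.068 g;
  quantisation to 1/128 g; summation per epoch. The three per-axis sums are
  combined by Euclidean norm by default (`sum_axes` available), since the
  axis-combination convention varies between implementations.

Both chains are computed on the whole recording and sliced on the epoch grid,
never filtered epoch-by-epoch — band-pass edge effects would otherwise
corrupt every epoch boundary. The package makes no claim of bit-exact
equality with any vendor implementation; validation is by property (linearity
of the chain below the truncation steps, additivity of epoch sums, zero
response to static input) and by an independent step-by-step recomputation
sharing the same constants.

## Exposures

**Imputation.** Epochs flagged non-wear or clipped receive the mean of the
valid values at the same time-of-day slot on the other recorded days, per
measure. Slots with no valid value on any day stay missing and count against
15-min coverage (a participant fails coverage when some 15-min period of the
24-h cycle contains a slot with no value on any day; assessed after
imputation). Imputed epochs do **not** count toward wear time: day validity
(> 16 h wear, strict) is judged on true wear only, so imputation cannot
manufacture valid days.

**AvAcc** is the arithmetic mean of the day's epoch values (wear + imputed);
participant AvAcc the unweighted mean over valid days; at least 3 valid days
are required.

**Intensity gradient.** Time accumulated (minutes) per intensity bin is
regressed on the bin midpoint on log-log axes by OLS; zero-time bins are
dropped (their log is undefined; an option stops at the last occupied bin
instead); fewer than 3 occupied bins leaves the day's IG undefined without
invalidating the day's AvAcc. The reference scheme is 25 mg-wide ENMO bins
from 0 to 4000 mg (ceiling configurable). For the other measures the
reference edges are mapped through a power model `t = a·r^b` fitted to paired
strictly positive epoch values on log-log axes (the "modelled" adjustment);
a degenerate fit (b ≤ 0) falls back to quantile-matched edges with a warning.
User-supplied edges are accepted verbatim to reproduce published schemes.

Two known small biases of this estimator are inherent to the binned log-log
regression, not implementation artifacts: wide low bins sit slightly above
the midpoint line (bin-averaging of a convex density), and sparsely occupied
top bins contribute Poisson noise in log counts. At 17 280 epochs/day the
recovered slope of a pure power-law day is within ~0.05–0.1 of the exponent.

**Exclusions** run in a fixed order: calibration error > 0.01 g; < 3 valid
days; 15-min coverage; ENMO AvAcc > 100 mg (both boundary rules strict); then
a percentile trim removing participants outside [0.5th, 99.5th] of ENMO AvAcc
*or* ENMO IG, with the percentiles computed on the set surviving the absolute
rules. The trim uses ENMO only and the surviving participant set is shared by
all four measures, keeping every downstream comparison on one cohort.

## Agreement

Pearson r with Fisher-z intervals (SE = 1/√(n−3); |r| = 1 reported as a point
interval rather than NaN). ICC(3,1) — two-way mixed effects, consistency,
single rater — from the two-way ANOVA decomposition, with exact F-bounds for
the interval. The ICC is computed for IG only: AvAcc inherits scale and unit
from its measure, so a consistency ICC across measures would conflate scale
with disagreement.

## Survival models

Both exposures are standardized (population-SD convention, switchable) and
entered as natural cubic splines — three internal knots at the 25th/50th/75th
percentile of values inside the boundary knots, boundary knots at the
5th/95th percentile; knots are placed per measure since each is standardized
separately. The basis is the truncated-power natural-spline construction
(K−1 columns for K knots, exactly linear beyond the boundary). Both spline
blocks plus covariates enter one Cox partial likelihood with **age as the
underlying timescale** and delayed entry at the age of wear (risk set at age
a: entry < a ≤ exit), Efron tie handling, fitted by lifelines with a
tightened Newton tolerance (1e-9) because the spline columns are collinear
enough that the default tolerance leaves visible wobble along flat
likelihood directions. BIC = −2·loglik + p·ln(events).

Hazard-ratio curves are `exp(f(s) − f(0))` with delta-method intervals,
referenced at 0 SD (the cohort mean) — the reference is configurable since
published figures rarely state it. Points beyond the boundary knots continue
linearly and are flagged as extrapolated.

**Diagnostics.** Schoenfeld residuals (one per event, explicit risk-set sums
honouring delayed entry) are scaled by d·Cov(β̂) and tested for association
with attained age by the Grambsch–Therneau statistic; martingale residuals
(Breslow baseline, per stratum) are regressed on each plain continuous
covariate and its square as a linearity check. Categorical covariates failing
the PH test at α = 0.05 trigger a refit with baseline hazards stratified on
them (their coefficients leave the model); continuous terms failing PH are
reported only — an optional time-interaction refit exists but is not part of
the default pipeline. The residual machinery is implemented in-package
because the library's residuals are unavailable for left-truncated fits; it
is calibrated by simulation (≈5% rejection under proportional hazards, ≥80%
power against an effect reversing sign mid-follow-up at n = 3000).

**Quadrant model.** Median splits of AvAcc and IG over the analysis cohort
(computed on the final analysis cohort; values equal to the median are
assigned "high") give four categories with low/low as reference, fitted with
the same covariates and timescale; at least 5 events per quadrant are
required.

**Complexity sweep.** The mutual model is refit with linear terms and 1–7
internal knots per exposure; the table reports BIC per configuration, with
per-row failures recorded rather than aborting.

## Synthetic data

The generator defines the package's study conditions; it emulates the
*structure* of wrist-accelerometer cohort data, not its biomechanics.

**raw_signal mode.** Gravity on z, white sensor noise (default SD 10 mg),
and per-epoch activity bursts: a sinusoid at the movement frequency (default
1 Hz) on the x-axis whose amplitude is drawn per epoch from a truncated power
law f(x) ∝ x^(−α) — drawing per epoch rather than per sample makes the
epoch-intensity distribution, and hence the true IG (−α over the burst
range), analytically known. Non-wear segments overwrite with the resting
orientation at one tenth the noise; calibration errors are applied as
measured = (true − offset)/scale so the calibration stage can recover them.
Not emulated: realistic movement spectra, posture and sleep, device-specific
noise colour, timestamp jitter. Tests passing on this signal therefore
validate the *processing contracts* (calibration recovery, masking, epoch
kernels), not performance on real human movement.

**epoch_level mode.** The fast path for cohort-scale work: 5 s ENMO epoch
values drawn directly from a rest/burst mixture (rest ≈ exponential with mean
0.3 mg; bursts power-law on 25–2000 mg, default α = 2.5), with participant
heterogeneity in rest fraction (SD 0.07 around 0.70) and exponent (SD 0.25)
so exposures vary across the cohort. With these defaults cohort AvAcc centres
near ~20 mg and IG near −2.1 to −2.5, i.e. the magnitudes seen in real
older-adult wrist cohorts. The other three measures derive from fixed
monotone power maps (MAD = 1.7·ENMO^0.95, MIMS = 0.023·ENMO^1.10,
Counts = 2.8·ENMO^1.05 — coefficients chosen so typical values land near each
measure's real-world scale) with multiplicative log-normal noise at epoch
level (SD 0.20) and participant level (SD 0.10), making between-measure
correlations imperfect by construction.

**Survival.** Entry ages uniform on 60–75 years (exercising delayed entry);
hazard h(a) = λ·e^(γa)·exp(β_A z_A + β_I z_I + covariate terms) with Gompertz
baseline λ = 2e-5/yr, γ = 0.09/yr (a realistic late-life mortality doubling
time of ~7.7 years) and administrative censoring at 85 — closed-form
integration gives an expected event fraction near 0.30 under these defaults.
Event ages come from exact inverse-transform sampling of the closed-form
cumulative hazard (no root finding); a two-piece variant flips one
covariate's effect sign at a chosen age to provide a controlled violation of
proportional hazards for power-testing the diagnostics. Default effect sizes
are β_AvAcc = −0.25 and β_IG = −0.20 per SD; covariate stand-ins are sex
(−0.3), a binary lifestyle factor (+0.4), a morbidity count (+0.25, the
"mediator" in the extended covariate set) and the season covariate — two
orthogonal sine functions of the wear start date's fractional day of year.

All randomness descends from one seed through keyed substreams
(`SeedSequence([seed, stage, participant])`), so stages rerun in isolation
reproduce their slice of a full run bit-for-bit.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` use desk-scale sizes chosen as the
package's own defaults: 300 participants × 5 days for end-to-end pipeline
runs; 17 280-epoch single days for IG recovery; 10 000 paired epochs for the
bin-adjustment fit; n = 2000 with ~30% events × 200 replicates for spline
effect-recovery and interval coverage; n = 3000 × 100 replicates for
diagnostics power; n = 1000 × 100 replicates for quadrant ordering. Raw-signal
runs in tests use 20 Hz recordings — the chain is sampling-rate-agnostic by
construction (everything is resampled internally), so the rate mainly scales
cost.

## Known limitations

* The filter-chain constants reproduce the cited algorithm *families*, not
  any particular vendor binary; absolute MIMS/Counts values are comparable
  within this package only.
* The non-wear detector cannot see still periods much shorter than its 60-min
  window (by design).
* PH-failing continuous covariates are reported, not repaired; the optional
  time-interaction refit is manual.
* The generator's activity process is a stationary rest/burst mixture: no
  diurnal rhythm, so the time-of-day imputation stage is exercised for
  correctness (means of same-slot values), not for realism of imputed values.
* Quadrant medians are data-driven; in small cohorts the split is noisy, and
  the package makes no attempt to stabilise it.
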