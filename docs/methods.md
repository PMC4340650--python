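# Methods

This note records the models, estimators and numerical choices behind
diauxkit, and what validation on synthetic data does and does not
establish.

## Batch-culture model

A glucose-fed batch culture is modeled as three sequential stages:

1. **Glucose phase** — biomass X (as calibrated OD) grows at μ_glc;
   glucose falls by (1/Y_X/glc)·dX and acetate rises by q_sec·dX
   (overflow secretion).
2. **Diauxic shift** — when glucose falls below 10⁻⁶ g/l the culture
   arrests for a fixed lag (no growth, no consumption).
3. **Acetate phase** — growth at μ_ace consuming the accumulated
   acetate by (1/Y_X/ace)·dX until exhaustion, then stationary phase.

A co-utilizing genotype instead grows in a single phase at μ_co,
drawing on glucose and acetate in proportion to their current
concentrations, with no secretion and no lag. A GFP reporter
accumulates as dG/dt = α·X with α switching from a low
exponential-phase value to a high value from the shift onward — the
surge is phenomenological, not a mechanistic cAMP–CRP model.

The integrator takes fixed 1-minute steps using exact per-step
exponential growth factors, so each phase is exactly exponential at
zero noise; output is down-sampled to the 10-minute readout grid.
Substrate depletion within a step is handled by capping growth at the
available pool, so the phase-boundary error is at most one internal
step. Measurement noise is applied per readout after the dynamics:
mean-preserving multiplicative lognormal noise on OD (coefficient of
variation `od_cv`), additive Gaussian noise on GFP, Gaussian noise on
simulated Ct values. One integer master seed spawns independent
`numpy` sub-streams per well/replicate; zero-noise output is
bit-identical regardless of seed.

### Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| μ_glc | 0.56 | h⁻¹ | measured glucose growth rate of the glycolysis-only ancestor |
| lag | 3.47 | h | measured diauxic shift of that ancestor |
| μ_ace | 0.17 | h⁻¹ | ≈0.3·μ_glc, the ratio used for the diauxie-detection validation scenario |
| Y_X/glc | 0.45 | OD per g/l | aerobic glucose biomass yield (≈0.45 g/g at ≈1 g/l per OD) |
| q_sec | 0.70 | g/l per OD | overflow secretion of ~0.3 g acetate per g glucose |
| Y_X/ace | 0.30 | OD per g/l | biomass yield on acetate, lower than on glucose |
| μ_co | 0.35 | h⁻¹ | co-utilizer default (slowed glucose transport) |
| α_exp / α_shift | 1800 / 9000 | GFP·OD⁻¹·h⁻¹ | GFP/OD ≈ α/μ in balanced growth, matching the 10³–10⁴ range of measured transcriptional activities; 5× surge at the shift |
| od_cv | 0.02 | — | typical plate-reader repeatability |
| culture | 1 g/l glucose, OD₀ 0.01, 24 h | | the serial-transfer growth condition |

Named genotypes for competition studies: `fast_secretor()` (μ_glc 1.0,
lag 1 h, q_sec 0.8 — an evolved fast-growing donor), `slow_coutilizer()`
(μ_co 0.82) and `coutilization_revertant()` (μ_glc 0.86, lag 3.47,
diauxic again). The co-utilizer rate was chosen by running the
passage simulator to its fixed point so that the cross-feeder settles
near the observed 10–13% frequency band while remaining invadable from
both sides; the revertant's rate is 30% above the co-utilizer's
glucose-limited effective rate but below the donor's, which drives it
extinct within six passages.

### What the generator does and does not emulate

It reproduces the statistical structure the estimators assume: phasewise
exponential growth, abrupt arrest/resumption, conserved substrate mass,
state-dependent reporter synthesis, log-linear Ct response, binomial
cytometry counts, and well-mixed shared substrate pools in co-culture.
It does **not** model inoculation lag, gradual metabolic transitions,
stationary-phase death, GFP maturation or bleaching, amplification-
efficiency drift, or demographic drift beyond count sampling. Passing
recovery tests on this generator therefore shows the estimators are
correct and calibrated *under their own assumptions*; real curves with
smooth shoulders or drifting baselines can behave worse.

## Growth-curve estimators

* **Window extraction.** Regressions use the first contiguous run of
  readouts with calibrated OD inside the inclusive bounds holding at
  least 5 points (stray single-readout dips into the window are
  skipped); no interpolation to the exact bounds. Five points mirrors
  the minimum used for the concentration-vs-biomass regressions.
* **Growth rate.** OLS of ln OD on time over OD 0.05–0.35. On exact
  exponentials the slope is recovered to numerical precision;
  calibration by a factor f shifts the intercept by ln f and leaves the
  slope unchanged.
* **Yield (max OD)** uses centered local-linear smoothing over 5
  readouts (50 min) to suppress single-readout spikes.
* **Diauxie detection.** Two independent fits — primary (OD 0.05–0.35)
  and extended (OD 0.05 to 0.9·max OD) — compared by a one-sided
  two-sample t statistic (μ₁−μ₂)/√(se₁²+se₂²) with Welch–Satterthwaite
  degrees of freedom; diauxic iff p ≤ α **and** the extended slope is
  lower. The windows are nested, which makes the test conservative
  under the single-phase null; measured specificity and sensitivity on
  the generator are ≥95% at 2% OD noise. When both fits are exact
  (zero residual), equal slopes give p = 1 and any slope deficit gives
  p = 0. A significantly *higher* extended slope sets a quality flag
  and classifies single-phase.
* **Shift duration.** The smoothed specific growth rate d(ln OD)/dt
  (local-linear, 5 readouts) is scanned after the primary window for a
  debounced fall below 0.1 h⁻¹; the arrest-plateau ln OD level is then
  averaged (trimming the smoothing-blurred tail), and the two
  boundaries are refined: the start as the intersection of the
  glucose-phase regression line with the plateau, the end by a
  piecewise plateau–ramp–plateau least-squares fit over every
  post-arrest readout (free parameters: resumption time, second-phase
  rate bounded below by the detection threshold, final rise), with
  multi-start to avoid the flat directions of change-point likelihoods.
  If the full-window rate never dips (very short lags blurred by
  smoothing), detection retries with a 3-readout window. On noiseless
  simulations the estimate is within ~0.03 h of truth across lags
  0.5–5 h. Under 2% OD noise the resumption boundary is the precision
  bottleneck: with the second phase as shallow and short as the default
  conditions produce (μ_ace 0.17 h⁻¹, ~0.2 ln-units of rise), the
  Cramér–Rao bound for the resumption time with unknown second-phase
  rate is ≈0.11 h, and the estimator operates at that bound — roughly
  85–90% of noisy curves land within one 10-min sampling interval of
  the true duration. Steeper or longer acetate phases localize the
  boundary much more precisely.
* The 0.1 h⁻¹ arrest threshold is absolute rather than a fraction of μ
  because fractional thresholds misbehave when the second-phase rate is
  small; it is configurable.

## Reporter dynamics

GFP/OD is computed pointwise with readouts below a 0.02-OD floor
dropped (the quotient is noise-dominated below it). The derivative for
promoter activity uses the same 5-readout local-linear estimator as the
growth module, on interior points only. Windowed summaries average the
first contiguous OD 0.1–0.3 run per replicate and combine replicates
with a t-based 95% CI. The CRP-activity ratio propagates the two CIs
to first order (relative errors in quadrature). Percent changes and
ratios reproduce printed-table formatting with half-away-from-zero
rounding (integers for percents, one decimal for ratios). Background
(blank-well) subtraction is available but off by default. In balanced
exponential growth dG/dt = αX gives G/X → α/μ; the construction tests
start the reporter in that balanced state so the identity is exact.

## Uptake and secretion rates

Yields are OLS slopes of concentration on OD over a stated
exponential-phase time window with ≥5 points; the window defaults to
the growth module's primary exponential window mapped to time. The
specific rate is |yield|·μ with the standard error combined to first
order from both inputs; the slope sign assigns the role (negative —
uptake, positive — secretion), and reported tables carry positive
magnitudes plus the role column. Units are g·l⁻¹·OD⁻¹·h⁻¹ throughout;
no molar conversion is applied by default. The co-utilization call
requires simultaneous uptake of both compounds at ≥0.01 g·l⁻¹·OD⁻¹·h⁻¹
on the same glucose-present window; two sub-threshold rates are
indeterminate rather than negative.

## qPCR

2^ΔΔCt assumes 100% amplification efficiency (exact base-2). Replicates
are aggregated as mean Ct before differencing; the CI comes from
per-replicate ΔΔCt values paired by index, mapped to the fold scale.

The allele-frequency standard curve supports two log-linear forms. The
default regresses the known fraction (percent) on log10 of mean Ct —
the frequency is inversely related to the logarithm of Ct — which makes
curve fitting and inversion exact inverses of the simulator at zero
noise and keeps the absolute error of recovered fractions roughly
constant (±1–3 points at 0.2-cycle noise) across the 5–100% range. The
conventional dilution-series form (Ct linear in log10 of template
fraction) is available behind the same `form` flag in both the
simulator and the fitter; under a physical −3.3 cycles/decade slope it
propagates 0.2-cycle noise to ~8 points at 100%, which is why it is not
the default for mixture standards. Zero-percent standards carry no
template for the allele-specific primer and are censored ("no
amplification"); censored points never enter fits, and a fully censored
measurement inverts to 0% with a flag. Frequency CIs combine the
replicate spread with the standard curve's OLS parameter covariance
propagated through the inversion; ignoring the curve term undercovers
noticeably at 3 replicates. Estimates are clamped to [0, 100] with a
flag.

## Competition statistics

* Generations per passage = log2(dilution): a culture diluted D-fold
  must double log2 D times to regrow, 9 at the 512-fold daily transfer
  (population bounds ~2×10⁶–10⁹ follow but are not asserted).
* Frequencies from cytometry counts use Wilson 95% intervals (good
  boundary coverage at the low fractions coexistence produces); totals
  below 45 000 counts are flagged.
* The coexistence call requires the trajectory tail (default 3
  passages) to sit inside [0.01, 0.99] with a span ≤ the band width;
  exclusion is a final fraction beyond the floor; anything else is
  undecided. The call is symmetric under relabeling f → 1−f.
* The Fisher test computes the hypergeometric tail of the top-left cell
  from log-factorial (gammaln) point masses, one-sided in the observed
  direction relative to the conditional expectation; both directed
  tails and a point-mass two-sided p are exposed. One-sided is the
  default because the diauxie contingency's printed probability equals
  the one-sided tail (the two-sided value would be about twice it).
* One-way ANOVA delegates to the standard decomposition; nested ANOVA
  tests the population effect against the isolate-within-population
  mean square (replicate measurements are pseudo-replicates of their
  isolate), with sequential sums of squares, groups before isolates,
  for unbalanced designs. Degenerate data (all values identical)
  return p = 1 with a flag rather than an exception in the nested
  design, where screening cohorts can be constant.
* Spearman p-values are exact (full enumeration over pairings) for
  n ≤ 8 and t-approximate beyond; Pearson uses the standard
  t-approximation.

## Validation problem sizes

The test suite and the reproduction script use 100-seed Monte-Carlo
batches for recovery/calibration checks, exhaustive enumeration of all
2×2 tables with total ≤ 24 for the Fisher oracle, 1000 simulations for
ANOVA null calibration, 12-passage competitions from four starting
fractions, and 6-passage exclusion runs — sizes at which the binomial
uncertainty of the measured rates is a few percent and the whole suite
runs in well under a minute per check on one CPU.

## Known limitations

* The shift-duration estimator's precision is set by the information in
  the second growth phase; shallow, short acetate phases (slow μ_ace,
  little secreted acetate) leave ~0.1 h of irreducible uncertainty at
  2% OD noise, as quantified above.
* The slope-equality test treats the primary and extended fits as
  independent although the windows are nested; this is conservative
  (under-rejects) rather than anticonservative.
* The competition simulator has no demographic drift beyond count
  sampling and assumes a well-mixed shared medium within each passage;
  bottleneck stochasticity at 512-fold dilution is not modeled.
* ΔΔCt assumes perfect efficiency and a single reference gene; no
  efficiency calibration or melt-curve handling is provided.
* Windowed summaries use the first contiguous OD run, so curves that
  re-enter the window (e.g. strong diauxie inside 0.1–0.3) contribute
  only their first passage through it.
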