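# Methods

## Model and assumptions

The package models the blood-glucose excursion of a tolerance test as the
free relaxation of a linearized glucose–hormone feedback loop.  Writing
`g(t) = G(t) − G0` for the deviation from the stabilized concentration,

    g'' + 2 α g' + ω₀² g = 0,    g(0) = μ − G0,    g'(0) = ν.

Assumptions built into this choice:

* **Impulsive forcing.**  The bolus (intraperitoneal glucose or insulin)
  is treated as instantaneous at `t = 0`; its effect is entirely absorbed
  into the fitted initial conditions `μ`, `ν`, and the equation on
  `t > 0` is homogeneous.  Fitting an "optimal initial condition" is only
  meaningful under this reading; a finite absorption phase would require
  a forcing term and is out of scope.
* **Linearity.**  The feedback is linearized around the fixed point, so
  the four rate constants of the underlying two-compartment
  glucose–hormone system are unidentifiable individually and are absorbed
  into `α` and `ω₀²`.  The hormone trajectory is never observed or
  reconstructed; the model is fitted to glucose alone, parameterized
  directly by `(α, ω₀², G0, μ, ν)`.
* **Stability.**  `α > 0`, `ω₀² > 0`, so both characteristic roots have
  negative real part and every curve relaxes to `G0`.  (`α = 0`, the
  undamped boundary, is accepted by the parameter container for analytic
  work but is outside the fitting bounds.)
* **One function class for both tests.**  GTT and ITT curves use the
  identical solution; only the feature naming differs (maximum versus
  minimum, decline versus recovery), implemented once with a sign
  convention.

The critical branch `α² = ω₀²` is detected with relative tolerance 1e−9
on `α²/ω₀²` and evaluated with the confluent form `(C₁ + C₂ t)e^{−αt}`,
avoiding the catastrophic cancellation of the overdamped formula near
equal roots; continuity across the boundary is property-tested.

## Time and units

Minutes internally everywhere: `α` in 1/min, `ω₀²` in 1/min², rates in
mmol/L/min, AUC in mmol·min/L.  The basic period `T_G = 2π/ω` alone is
reported in hours, matching how such periods are usually tabulated.
Feature tables report rates per minute.

## Fitting

Five parameters from eight points, by bounded trust-region least squares
(`scipy.optimize.least_squares`, method `trf`).  The objective is
multimodal across the overdamped/underdamped boundary, so the optimizer
is started from a deterministic grid — `α ∈ {0.005, 0.02, 0.05, 0.1,
0.2}` 1/min crossed with `ω₀² ∈ {0.25, 0.5, 1, 2, 4}·α²`, which places
starts on both sides of the critical manifold — plus 8 random restarts
drawn from a generator seeded by the configuration; `μ` starts at the
first reading, `G0` at the last, `ν` at the first finite difference.
Bounds are physiologic for rat glycemia: `α ∈ [1e−4, 1]` 1/min,
`ω₀² ∈ [1e−8, 1]` 1/min², `G0 ∈ [1, 15]` mmol/L, `μ ∈ [1, 35]` mmol/L,
`ν ∈ [−5, 5]` mmol/L/min.  The best converged start by RSS is reported;
adding starts can never worsen the result (property-tested).  Everything
is deterministic given data, configuration and seed.

Diagnostics: RSS; `R² = 1 − RSS/TSS` (−∞ marker for a zero-variance
series with nonzero residual); `EstVar = RSS/(m − 5)`, using the number
of free parameters (5) in the denominator.  A constant series is
degenerate — it is reproduced exactly with `μ = G0`, `ν = 0` but flagged
unacceptable, since `α` and `ω₀²` are then unconstrained.  Curves with
fewer than 6 points are rejected (no residual degrees of freedom).

### Acceptability gate

Real cohorts contain curves the single-excursion model cannot represent
(notably biphasic, two-peak glucose responses).  A fit is `acceptable`
when all of the following hold; each threshold is configurable and the
gate decision is logged:

1. the optimizer converged;
2. `R² ≥ 0.8`;
3. the residual-sign sequence is not extreme under the exact
   Wald–Wolfowitz runs test (two-sided p ≥ 0.05).  At m = 8 points this
   screen is intentionally lenient — the exact runs null is so coarse
   that no 8-point sign pattern reaches the 2.5% tail — and it becomes
   informative for longer series;
4. an underdamped fit must describe a genuinely relaxing excursion: its
   envelope `e^{−αT}` over the observation window `T` must decay to at
   most 0.5.  Without this screen the optimizer can "fit" a two-peak
   curve with a near-undamped ring (`α` at its lower bound, period
   ≈ 40 min) that tracks the sampled points while predicting glucose
   oscillating indefinitely — outside the model's physiologic premise
   that the test observes the return to stabilized glycemia.  Overdamped
   and critical fits have at most one interior extremum and cannot
   emulate a ring, so they are not screened; this also tolerates the
   common and legitimate case of an insulin-test fit whose stabilized
   level is only weakly identified beyond the 180-min window.

Fits may be run per animal (default) or on a group-mean curve; both
modes exist because published group tables can come from either.

## Feature extraction

All features come from the fitted parameters through the analytic
derivatives.  Stationary points and inflections are located by a
sign-change scan at 0.5-min resolution over the test window followed by
Brent root refinement to 1e−10 min; curves in this family are smooth
with widely separated roots at physiologic parameters, so the scan step
cannot straddle two roots.  The extremum is the *first* interior
stationary point with the right curvature (maximum for GTT, minimum for
ITT); later oscillations of an underdamped fit are ignored, since a
single extremum and inflection per curve is what the analysis reports.
The inflection `t_I` is the first zero of `G''` after the extremum, where
the return toward baseline is fastest; `G'_I = G'(t_I)` is negative for a
GTT decline and positive for an ITT recovery.  A curve with no interior
stationary point is boundary-flagged (`t_ext = 0`, `g_ext = μ`); features
whose defining root does not exist in the window are `None`, never
fabricated.

Model AUC integrates the closed form analytically (per-branch
antiderivatives) over the protocol window — 240 min for GTT, 180 min for
ITT, so it is directly comparable to the classical trapezoidal AUC — and
is cross-checked against adaptive quadrature at every call (the analytic
value is returned; disagreement raises).

## Classical arm

Trapezoidal AUC on the raw points (`numpy.trapezoid`; exact for
piecewise-linear data, duplicate times rejected).  Shapiro–Wilk
normality screening is advisory only: the comparison is nonparametric
regardless, matching standard practice for n = 10 groups.  Group
contrasts use the two-sided Mann–Whitney U test — exact when both groups
have ≤ 8 observations without ties, otherwise the normal approximation
with mid-rank tie correction (glucometer readings are discretized to
0.1 mmol/L, so ties happen) — under Bonferroni correction with k = the
number of requested contrasts; the default contrast set is the two
within-sex, across-age comparisons, at α = 0.05.  Glycemic bands:
normoglycemia 4.2–5.5 mmol/L inclusive, severe hypoglycemia below
2.2 mmol/L.

## Synthetic cohorts

The generator emulates the study design the package targets: four rat
groups (young/adult × male/female), ten animals per group, glucose read
at 8 points on the protocol grids (GTT 0–240 min, ITT 0–180 min).  Per
animal, group-true parameters are jittered — lognormal factors with
log-sd 0.1 on `α` and `ω₀²`, additive Normal(0, 0.2 mmol/L) shifts on
`G0` and `μ` — then evaluated on the grid, perturbed with homoscedastic
Gaussian measurement noise (default sd 0.3 mmol/L, glucometer scale) and
rounded to 0.1 mmol/L, the read-out resolution of a consumer glucometer;
noiseless cohorts are left unrounded (they are the ideal curves).
Non-positive draws are resampled.  Inter-animal variability is not
identifiable from published group-level summaries, so the jitter
magnitudes are declared defaults, not estimates.

**Calibration.**  The group-true parameters were derived by numerically
inverting the feature extractor: with `α`, `G0`, `μ` fixed at physiologic
values per group, `ω₀²` (and for ITT additionally `ν`) was solved so that
the noiseless curve reproduces each group's anchor inflection time
`t_I` exactly (GTT: 82.0, 23.1, 44.3, 19.6 min; ITT: 122.6, 102.4,
135.7, 91.5 min for young-male, adult-male, young-female, adult-female
respectively) and, for ITT, a physiologic nadir — males above the
hypoglycemia threshold, young females inside the severe band
(G_min = 1.8 mmol/L < 2.2).  The frozen parameter table is a synthetic
calibration fixture, not fitted animal data; tests against these anchors
guard fixture integrity, not rediscovery.

**Biphasic contaminant.**  A configurable fraction of animals (default
0.7 of the young-female GTT group, echoing a 3-in-10 fit rate) receive a
two-peak curve instead: the sum of two damped-oscillatory excursions,
the second with onset delayed uniformly by 30–45 min, giving a first
peak near 15 min, a dip, a second peak near 45–70 min, and a return to
baseline by 240 min.  The default component shapes were selected, within
that morphology, to be maximally inconsistent with any single-excursion
fit (best achievable R² ≤ ≈0.74 across delays), so the contaminant
exercises the gate rather than sneaking through it.  It is a test
fixture: the package deliberately does not model biphasic responses.

## What the synthetic data do and do not show

Passing tests on synthetic cohorts demonstrate that the estimation,
feature-extraction and comparison machinery is correct for data generated
by the model class plus i.i.d. Gaussian glucometer noise, and that the
gate separates that class from a specific two-peak alternative.  Real
tolerance-test data differ in ways the generator does not emulate:
absorption is not impulsive, noise can be heteroscedastic and autocorrelated,
inter-animal variation is richer than independent parameter jitter, and
model-violating shapes are more varied than the fixed contaminant.
Results on synthetic data therefore validate the software and the
identifiability of the procedure — not the biological adequacy of the
model for any particular cohort.

## Numerical choices

* Critical-branch tolerance 1e−9 (relative, on `α²/ω₀²`); confluent
  evaluation inside the band.
* Root scan step 0.5 min; Brent refinement tolerance 1e−10 min.
* AUC quadrature cross-check tolerance 1e−6 relative.
* `G(0) = μ` and `G'(0) = ν` are pinned exactly at `t = 0` (no
  floating-point round trip through the branch coefficients).
* Exact Mann–Whitney only for tie-free samples with both n ≤ 8;
  mid-ranks plus tie-corrected normal approximation otherwise.
* Problem sizes in the validation suite (50–100 oracle draws, 100
  noisy-recovery replicates, ≈500 animals for gate rates) were chosen as
  the smallest sizes at which the checked rates are statistically stable.

## Known limitations

* The hormone compartment is never reconstructed; `α` and `ω₀²` are
  effective constants whose mechanistic decomposition is unidentifiable
  from glucose alone.
* With 8 points and 5 parameters, `G0` can be weakly identified when the
  curve has not relaxed within the window (slow overdamped tails); such
  fits are reported with their diagnostics rather than suppressed.
* The runs-test screen is uninformative at m = 8 (see above); gate
  behaviour at protocol size rests on the R² and ring screens.
* No parameter standard errors or confidence intervals are computed, and
  no mixed-effects pooling across animals; fits are independent per
  curve.
* Biphasic curves are detected and excluded, not modelled.
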