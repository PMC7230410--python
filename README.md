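# glycofit

Model-based analysis of glucose (GTT) and insulin (ITT) tolerance tests in
rodents.

A tolerance test perturbs blood glucose with a bolus (glucose or insulin)
and samples the return to stable glycemia at a handful of time points.
The conventional summary — area under the curve by the trapezoidal rule,
compared between groups with rank tests — collapses the whole response
into one number.  `glycofit` instead fits each curve with the closed-form
solution of a damped linear glucose–hormone feedback model and reads off
physiologically interpretable characteristics: initial rate, peak (or
nadir) and its time, the inflection where glucose returns fastest toward
baseline, the stabilized level, the oscillation period, and a model-based
AUC.  The classical arm is included alongside, so both analyses run from
the same data.

It is intended for metabolic-phenotyping work: analysts with per-animal
glucose time series (8 readings per test) who want per-curve model
parameters, curve features, fit-quality gating and group comparisons —
plus a calibrated synthetic cohort generator so the whole pipeline can be
exercised and validated without animal data.

## Model

Let `G(t)` be blood glucose (mmol/L) at `t` minutes after the bolus and
`G0` the stabilized concentration the animal relaxes to.  Linearizing the
glucose–hormone feedback around its fixed point, the deviation
`g(t) = G(t) − G0` satisfies a second-order constant-coefficient ODE

    g'' + 2 α g' + ω₀² g = 0,        g(0) = μ − G0,   g'(0) = ν

with damping coefficient `α` (1/min) and squared natural frequency `ω₀²`
(1/min²); the bolus enters as an impulse absorbed into the fitted initial
conditions `μ = G(0)`, `ν = G'(0)`.  The characteristic equation
`r² + 2αr + ω₀² = 0` selects the solution branch:

* **overdamped** (`α² > ω₀²`): `G(t) = G0 + C₁ e^{r₁ t} + C₂ e^{r₂ t}`,
  two distinct negative real roots;
* **underdamped** (`α² < ω₀²`): `G(t) = G0 + e^{−αt} (A cos ωt + B sin ωt)`
  with `ω = √(ω₀² − α²)` and basic period `T_G = 2π/ω`;
* **critical** (`α² = ω₀²`): `G(t) = G0 + (C₁ + C₂ t) e^{−αt}`.

The five parameters `(α, ω₀², G0, μ, ν)` are identified per curve by
multi-start bounded nonlinear least squares, with RSS, R² and
`EstVar = RSS/(m−5)` as diagnostics and an acceptability gate that flags
curves outside the single-excursion model class (e.g. biphasic two-peak
responses).  Derived features follow from the analytic derivatives:
`t_max`/`G_max` (GTT) or `t_min`/`G_min` (ITT) at the first admissible
stationary point, and `t_I`/`G'_I` at the inflection after it — the
moment of fastest return toward baseline.

## Worked example

Simulate one adult-male GTT curve from the calibrated presets and fit it:

```python
from glycofit import GlucoseResponseModel, generate_cohort, calibrated_presets

presets = [p for p in calibrated_presets(n_animals=1)
           if p.group == "adult_male" and p.test == "GTT"]
ts = generate_cohort(presets, seed=42)[0]
res = GlucoseResponseModel(ts).fit()
print(res.summary())
```

```
Glucose response model fit
==============================================
subject: adult_male_GTT_m01 group: adult_male
test:    GTT            points: 8
regime:  underdamped    converged: True
acceptable fit: True
----------------------------------------------
alpha          0.061049  1/min
omega0_sq      0.006822  1/min^2
G0               6.5563  mmol/L
mu = G(0)        5.4028  mmol/L
nu = G'(0)       0.6788  mmol/L/min
----------------------------------------------
RSS              0.1444  mmol^2/L^2
R^2              0.9874
EstVar           0.0481
G_max            9.4897  mmol/L at t = 15.2 min
G'_I            -0.1077  mmol/L/min at t_I = 28.5 min
T_G               1.882  h
model AUC        1652.4  mmol*min/L over 240 min
```

Reading: this animal started at 5.4 mmol/L fasting glucose, rose at
0.68 mmol/L/min, peaked at 9.5 mmol/L around 15 min, cleared glucose
fastest (−0.11 mmol/L/min) at the inflection 28.5 min, and relaxes to a
stabilized 6.6 mmol/L; R² of 0.99 and an unremarkable residual pattern
make it an acceptable single-excursion fit.

The same analysis runs end to end from the shell:

```bash
glycofit simulate --seed 42 --out cohort.csv          # 4 groups x GTT+ITT
glycofit report --input cohort.csv --outdir results --seed 42
```

writing `fits.csv`, `features.csv`, `classical_auc.csv`,
`comparisons.json` (trapezoidal AUCs with Mann–Whitney contrasts under
Bonferroni correction) and a run log.

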