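"""Protocol-faithful synthetic tolerance-test cohorts.

The study design being emulated: four rat groups (young/adult x
male/female), ten animals per group, glucose read at 8 time points per
test (GTT grid 0..240 min, ITT grid 0..180 min).  No raw measurements are
public, so every downstream module is exercised on cohorts generated here.

Each group carries true model parameters; each animal perturbs them with
lognormal jitter on the rate constants (alpha, omega0_sq) and additive
normal jitter on the concentration levels (G0, mu), then adds i.i.d.
Gaussian measurement noise and rounds to 0.1 mmol/L — the resolution of a
consumer glucometer.  An optional biphasic contaminant replaces a
fraction of animals with a two-peak curve (sum of two damped-oscillatory
excursions, the second with delayed onset), emulating the young-female
glucose-load curves that fall outside the single-response model class.
Generation is fully reproducible from an explicit seed.

Group-level true parameters in :func:`calibrated_presets` were
derived by numerically inverting the feature extractor so that the
noiseless curve of each group reproduces that group's anchor inflection
time t_I (and, for young females under insulin, a nadir in the
life-threatening hypoglycemia band); they are synthetic calibration
fixtures, not fitted animal data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .fitting import GROUPS, GTT_GRID, ITT_GRID, TimeSeries
from .model import ModelParameters, evaluate

__all__ = [
    "GroupPreset",
    "BiphasicShape",
    "generate_cohort",
    "calibrated_presets",
    "CALIBRATION_TARGETS_T_I",
]

#: anchor inflection times t_I (minutes) the synthetic groups are calibrated to
CALIBRATION_TARGETS_T_I = {
    ("young_male", "GTT"): 82.0,
    ("adult_male", "GTT"): 23.1,
    ("young_female", "GTT"): 44.3,
    ("adult_female", "GTT"): 19.6,
    ("young_male", "ITT"): 122.6,
    ("adult_male", "ITT"): 102.4,
    ("young_female", "ITT"): 135.7,
    ("adult_female", "ITT"): 91.5,
}

GLUCOMETER_RESOLUTION = 0.1  # mmol/L


@dataclass(frozen=True)
class BiphasicShape:
    """Two-peak contaminant: a second damped excursion with delayed onset.

    Both components are damped-oscillatory deviations
    ``(nu/w) * exp(-a t) * sin(w t)`` added to the baseline; the second
    starts after a per-animal delay drawn uniformly from
    ``onset_delay_min``.  Defaults place the first peak near 15 min and
    the second near 60 min with a dip between, the two-peak morphology of
    young-female glucose loads.
    """

    a1: float = 0.07  # 1/min
    w1: float = 0.08  # rad/min
    nu1: float = 1.568  # mmol/L/min
    a2: float = 0.03
    w2: float = 0.06
    nu2: float = 0.525
    onset_delay_min: tuple = (30.0, 45.0)
    baseline: float = 5.5  # mmol/L


@dataclass(frozen=True)
class GroupPreset:
    """Generative recipe for one animal group under one test."""

    group: str
    test: str
    truth: ModelParameters
    noise_sd: float = 0.3  # mmol/L, homoscedastic glucometer noise
    biphasic_fraction: float = 0.0
    n_animals: int = 10
    biphasic_shape: BiphasicShape = field(default_factory=BiphasicShape)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.test not in ("GTT", "ITT"):
            raise ValueError(f"test must be GTT or ITT, got {self.test!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.biphasic_fraction <= 1.0:
            raise ValueError("biphasic_fraction must be in [0, 1]")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")

    @property
    def grid(self) -> np.ndarray:
        return np.array(GTT_GRID if self.test == "GTT" else ITT_GRID)


def _damped_excursion(t: np.ndarray, a: float, w: float, nu: float) -> np.ndarray:
    """Deviation of an underdamped curve started at its baseline."""
    return (nu / w) * np.exp(-a * t) * np.sin(w * t)


def _biphasic_curve(t: np.ndarray, shape: BiphasicShape, delay: float) -> np.ndarray:
    y = shape.baseline + _damped_excursion(t, shape.a1, shape.w1, shape.nu1)
    t2 = np.clip(t - delay, 0.0, None)
    return y + _damped_excursion(t2, shape.a2, shape.w2, shape.nu2)


def _jittered(
    truth: ModelParameters,
    rng: np.random.Generator,
    rate_sd: float,
    level_sd: float,
) -> ModelParameters:
    """Per-animal parameter perturbation around the group truth."""
    if rate_sd == 0.0 and level_sd == 0.0:
        return truth
    return ModelParameters(
        alpha=truth.alpha * float(rng.lognormal(0.0, rate_sd)),
        omega0_sq=truth.omega0_sq * float(rng.lognormal(0.0, rate_sd)),
        g_stab=truth.g_stab + float(rng.normal(0.0, level_sd)),
        mu=max(truth.mu + float(rng.normal(0.0, level_sd)), 0.5),
        nu=truth.nu,
    )


def generate_cohort(
    presets: Sequence[GroupPreset],
    seed: int,
    jitter_rate_sd: float = 0.1,
    jitter_level_sd: float = 0.2,
    round_to: Optional[float] = GLUCOMETER_RESOLUTION,
) -> List[TimeSeries]:
    """Simulate one curve per animal for every preset, reproducibly.

    For each animal the group truth is jittered (lognormal factors with
    log-sd ``jitter_rate_sd`` on alpha and omega0_sq, additive normal
    shifts of sd ``jitter_level_sd`` mmol/L on G0 and mu), evaluated on
    the protocol grid, perturbed with i.i.d. ``Normal(0, noise_sd^2)``
    measurement error and rounded to ``round_to`` mmol/L.  Draws leading
    to non-positive glucose are resampled.  The first
    ``round(biphasic_fraction * n_animals)`` animals of a preset instead
    receive the two-peak contaminant curve.  Identical seeds give
    byte-identical cohorts.
    """
    rng = np.random.default_rng(seed)
    cohort: List[TimeSeries] = []
    for preset in presets:
        t = preset.grid
        n_biphasic = int(round(preset.biphasic_fraction * preset.n_animals))
        for i in range(preset.n_animals):
            if i < n_biphasic:
                delay = float(rng.uniform(*preset.biphasic_shape.onset_delay_min))
                clean = _biphasic_curve(t, preset.biphasic_shape, delay)
            else:
                animal = _jittered(preset.truth, rng, jitter_rate_sd, jitter_level_sd)
                clean = np.asarray(evaluate(animal, t))
            for _ in range(100):
                y = clean + rng.normal(0.0, preset.noise_sd, size=len(t))
                if round_to and preset.noise_sd > 0:
                    # glucometer read-out: quantized to 0.1 mmol/L; a
                    # noiseless cohort is the ideal curve, left unrounded
                    y = np.round(np.round(y / round_to) * round_to, 10)
                if np.all(y > 0):
                    break
            else:  # pathological preset: clamp rather than loop forever
                y = np.maximum(y, round_to or 0.1)
            tag = "b" if i < n_biphasic else "m"
            cohort.append(
                TimeSeries(
                    subject_id=f"{preset.group}_{preset.test}_{tag}{i + 1:02d}",
                    group=preset.group,
                    test=preset.test,
                    times=t.copy(),
                    glucose=y,
                )
            )
    return cohort


# Group truths derived by inverting the feature extractor against the
# t_I anchors (see module docstring).  Values are frozen so the
# presets are stable fixtures; provenance: numerical inversion of
# extract_features over omega0_sq with the remaining parameters set to
# physiologic rat glycemia.
_CALIBRATED_TRUTH = {
    # (group, test): (alpha 1/min, omega0_sq 1/min^2, g_stab, mu mmol/L, nu mmol/L/min)
    ("young_male", "GTT"): (0.02, 0.00077415183, 5.8, 5.2, 0.25),
    ("adult_male", "GTT"): (0.08, 0.008702578, 6.3, 5.8, 0.9),
    ("young_female", "GTT"): (0.04, 0.0021447383, 5.0, 5.4, 0.4),
    ("adult_female", "GTT"): (0.09, 0.012054427, 6.0, 5.6, 2.0),
    ("young_male", "ITT"): (0.015, 0.00033776554, 5.3, 6.0, -0.116773),
    ("adult_male", "ITT"): (0.018, 0.00049672854, 5.4, 6.2, -0.138592),
    ("young_female", "ITT"): (0.012, 0.00030672163, 4.6, 5.5, -0.126211),
    ("adult_female", "ITT"): (0.02, 0.00060964581, 5.0, 5.8, -0.177517),
}


def calibrated_presets(
    n_animals: int = 10,
    noise_sd: float = 0.3,
    young_female_gtt_biphasic_fraction: float = 0.7,
) -> List[GroupPreset]:
    """The eight calibrated presets (4 groups x GTT/ITT).

    Noiseless curves from these truths reproduce each group's anchor
    inflection time t_I within 2 minutes, and the young-female insulin
    response dips into the severe-hypoglycemia band (< 2.2 mmol/L).
    Young-female glucose loads carry a biphasic contaminant fraction
    defaulting to 0.7, echoing the 3-in-10 fit rate of that group.
    """
    presets = []
    for (group, test), values in _CALIBRATED_TRUTH.items():
        truth = ModelParameters(*values)
        frac = (
            young_female_gtt_biphasic_fraction
            if (group, test) == ("young_female", "GTT")
            else 0.0
        )
        presets.append(
            GroupPreset(
                group=group,
                test=test,
                truth=truth,
                noise_sd=noise_sd,
                biphasic_fraction=frac,
                n_animals=n_animals,
            )
        )
    return presets
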