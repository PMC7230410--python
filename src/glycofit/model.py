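"""Closed-form glucose response curve for tolerance-test modelling.

The blood-glucose excursion after a glucose or insulin bolus is modelled as
the relaxation of a linear glucose--hormone feedback loop.  Writing
``g(t) = G(t) - G0`` for the deviation of glucose from its stabilized level
``G0``, the linearized feedback dynamics reduce to a homogeneous
second-order ODE with constant coefficients::

    g'' + 2*alpha*g' + omega0_sq * g = 0,      g(0) = mu - G0,  g'(0) = nu

where ``alpha`` (1/min) is the damping coefficient and ``omega0_sq``
(1/min^2) the squared natural frequency of the loop.  The bolus itself is
treated as an impulse at t = 0, absorbed into the fitted initial conditions
``mu = G(0)`` and ``nu = G'(0)``; the equation on t > 0 is homogeneous.

The characteristic equation ``r^2 + 2*alpha*r + omega0_sq = 0`` selects the
solution branch:

* overdamped  (alpha^2 > omega0_sq): two distinct negative real roots,
  ``G(t) = G0 + C1*exp(r1 t) + C2*exp(r2 t)``;
* underdamped (alpha^2 < omega0_sq): conjugate complex roots, a decaying
  oscillation ``G(t) = G0 + exp(-alpha t) (A cos(w t) + B sin(w t))`` with
  damped frequency ``w = sqrt(omega0_sq - alpha^2)``;
* critical    (alpha^2 = omega0_sq): confluent form
  ``G(t) = G0 + (C1 + C2 t) exp(-alpha t)``.

With alpha > 0 and omega0_sq > 0 both roots have negative real part, so
every curve relaxes to ``G0``; this is the physiologic requirement that a
tolerance test ends back at stabilized glycemia.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Union

import numpy as np

__all__ = [
    "ModelParameters",
    "Regime",
    "RootInfo",
    "classify_regime",
    "evaluate",
    "derivative",
    "period",
]

#: Relative tolerance on alpha^2 / omega0_sq deciding the critical branch.
#: Near-equal roots make the overdamped formula cancel catastrophically, so
#: a thin band around the boundary is evaluated with the confluent form.
CRITICAL_TOL = 1e-9


class Regime(str, Enum):
    """Root structure of the characteristic equation."""

    OVERDAMPED = "overdamped"
    UNDERDAMPED = "underdamped"
    CRITICAL = "critical"


@dataclass(frozen=True)
class ModelParameters:
    """Parameters of the glucose response curve.

    Attributes
    ----------
    alpha : float
        Damping coefficient, 1/min; must be >= 0.  Fitted curves have
        alpha > 0 (decay to ``g_stab``); alpha = 0 is the undamped
        boundary (pure oscillator), admitted for analytic work.
    omega0_sq : float
        Squared natural frequency, 1/min^2; must be > 0.
    g_stab : float
        Stabilized glucose concentration G0, mmol/L (the curve's asymptote).
    mu : float
        Modelled initial glucose G(0), mmol/L; must be > 0.
    nu : float
        Modelled initial rate G'(0), mmol/L/min.
    """

    alpha: float
    omega0_sq: float
    g_stab: float
    mu: float
    nu: float

    def __post_init__(self) -> None:
        vals = (self.alpha, self.omega0_sq, self.g_stab, self.mu, self.nu)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite model parameters: {vals}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.omega0_sq <= 0:
            raise ValueError(f"omega0_sq must be > 0, got {self.omega0_sq}")
        if self.mu <= 0:
            raise ValueError(f"mu (initial glucose) must be > 0, got {self.mu}")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.alpha, self.omega0_sq, self.g_stab, self.mu, self.nu]
        )

    @classmethod
    def from_array(cls, x) -> "ModelParameters":
        a, w2, g0, mu, nu = (float(v) for v in x)
        return cls(alpha=a, omega0_sq=w2, g_stab=g0, mu=mu, nu=nu)


@dataclass(frozen=True)
class RootInfo:
    """Roots of ``r^2 + 2*alpha*r + omega0_sq = 0`` and the regime they imply.

    ``r1``/``r2`` are set in the overdamped and critical regimes (equal in
    the latter); ``omega`` is the damped angular frequency
    ``sqrt(omega0_sq - alpha^2)`` in the underdamped regime and ``None``
    otherwise.
    """

    regime: Regime
    r1: Union[float, None] = None
    r2: Union[float, None] = None
    omega: Union[float, None] = None


def classify_regime(params: ModelParameters, tol: float = CRITICAL_TOL) -> RootInfo:
    """Classify the characteristic-equation root structure.

    Overdamped iff ``alpha^2 > omega0_sq * (1 + tol)``, underdamped iff
    ``alpha^2 < omega0_sq * (1 - tol)``, critical in the band between.
    """
    a2 = params.alpha**2
    w2 = params.omega0_sq
    if a2 > w2 * (1.0 + tol):
        d = math.sqrt(a2 - w2)
        r1 = -params.alpha + d
        r2 = -params.alpha - d
        return RootInfo(regime=Regime.OVERDAMPED, r1=r1, r2=r2)
    if a2 < w2 * (1.0 - tol):
        return RootInfo(regime=Regime.UNDERDAMPED, omega=math.sqrt(w2 - a2))
    return RootInfo(regime=Regime.CRITICAL, r1=-params.alpha, r2=-params.alpha)


def _coefficients(params: ModelParameters, info: RootInfo):
    """Branch coefficients fixed by G(0) = mu and G'(0) = nu."""
    g0 = params.mu - params.g_stab  # initial deviation from the asymptote
    if info.regime is Regime.OVERDAMPED:
        r1, r2 = info.r1, info.r2
        c2 = (params.nu - r1 * g0) / (r2 - r1)
        c1 = g0 - c2
        return c1, c2
    if info.regime is Regime.UNDERDAMPED:
        a = g0
        b = (params.nu + params.alpha * g0) / info.omega
        return a, b
    # critical: (C1 + C2 t) e^{-alpha t}
    return g0, params.nu + params.alpha * g0


def evaluate(params: ModelParameters, t) -> np.ndarray:
    """Glucose G(t) in mmol/L at time(s) ``t`` (minutes, >= 0).

    Accepts a scalar or array of times; returns the same shape.  Exactly
    satisfies G(0) = mu and G(t) -> g_stab as t -> infinity.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    info = classify_regime(params)
    c1, c2 = _coefficients(params, info)
    if info.regime is Regime.OVERDAMPED:
        g = c1 * np.exp(info.r1 * t) + c2 * np.exp(info.r2 * t)
    elif info.regime is Regime.UNDERDAMPED:
        w = info.omega
        g = np.exp(-params.alpha * t) * (c1 * np.cos(w * t) + c2 * np.sin(w * t))
    else:
        g = (c1 + c2 * t) * np.exp(-params.alpha * t)
    out = params.g_stab + g
    out = np.where(t == 0.0, params.mu, out)  # G(0) = mu exactly
    return out if out.ndim else float(out)


def derivative(params: ModelParameters, t, order: int = 1) -> np.ndarray:
    """Analytic first or second derivative of :func:`evaluate`.

    ``order=1`` returns G'(t) in mmol/L/min (so ``derivative(p, 0, 1) == nu``
    exactly); ``order=2`` returns G''(t) in mmol/L/min^2.
    """
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    info = classify_regime(params)
    c1, c2 = _coefficients(params, info)
    a = params.alpha
    if info.regime is Regime.OVERDAMPED:
        r1, r2 = info.r1, info.r2
        p1, p2 = (r1, r2) if order == 1 else (r1**2, r2**2)
        out = c1 * p1 * np.exp(r1 * t) + c2 * p2 * np.exp(r2 * t)
    elif info.regime is Regime.UNDERDAMPED:
        w = info.omega
        e = np.exp(-a * t)
        cos, sin = np.cos(w * t), np.sin(w * t)
        # g' = e^{-at} [ (c2 w - c1 a) cos - (c1 w + c2 a) sin ]
        d1c = c2 * w - c1 * a
        d1s = -(c1 * w + c2 * a)
        if order == 1:
            out = e * (d1c * cos + d1s * sin)
        else:
            d2c = d1s * w - d1c * a
            d2s = -(d1c * w + d1s * a)
            out = e * (d2c * cos + d2s * sin)
    else:
        e = np.exp(-a * t)
        if order == 1:
            out = e * (c2 - a * (c1 + c2 * t))
        else:
            out = e * (a**2 * (c1 + c2 * t) - 2 * a * c2)
    if order == 1:
        out = np.where(t == 0.0, params.nu, out)  # G'(0) = nu exactly
    return out if out.ndim else float(out)


def period(params: ModelParameters) -> Union[float, None]:
    """Basic period T_G of the glucose oscillation, in hours.

    Defined only in the underdamped regime, where the curve rings at damped
    frequency ``omega``: ``T_G = 2*pi/omega`` minutes, returned in hours.
    Overdamped and critical curves do not oscillate; returns ``None``.
    """
    info = classify_regime(params)
    if info.regime is not Regime.UNDERDAMPED:
        return None
    return (2.0 * math.pi / info.omega) / 60.0
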