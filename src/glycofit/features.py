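"""Derived characteristics of a fitted glucose response curve.

Given fitted parameters, the curve summarised in the field's usual terms:
the initial glucose G(0) and initial rate G'(0), the post-bolus extremum
(G_max/t_max for a glucose load, G_min/t_min for an insulin bolus), the
inflection after the extremum where glucose changes fastest back towards
baseline (G'_I at time t_I), the stabilized level G0, the basic period T_G
of any ringing, and the model AUC over the test window.

Stationary points and inflections are located on the analytic derivatives:
a sign-change scan at 0.5-min resolution over (0, horizon] followed by
bracketed root refinement.  Curves in this model class are smooth with
widely separated roots at physiologic parameters, so the scan step is safe.
When a feature does not exist inside the window (e.g. a monotone curve has
no interior extremum) the corresponding field is ``None`` — features are
never fabricated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .model import (
    ModelParameters,
    Regime,
    _coefficients,
    classify_regime,
    derivative,
    evaluate,
    period,
)

__all__ = ["CurveFeatures", "extract_features", "model_auc"]

GTT_HORIZON_MIN = 240.0  #: glucose tolerance test window, minutes
ITT_HORIZON_MIN = 180.0  #: insulin tolerance test window, minutes

_SCAN_STEP_MIN = 0.5
_ROOT_XTOL_MIN = 1e-10


@dataclass(frozen=True)
class CurveFeatures:
    """Derived characteristics of one modelled tolerance-test curve.

    ``g_extremum``/``t_extremum`` are G_max/t_max for GTT and G_min/t_min
    for ITT.  ``g_rate_I`` is the extremal slope at the inflection t_I:
    the maximum speed of glucose decline for GTT (negative) or of recovery
    for ITT (positive).  ``extremum_at_boundary`` marks curves with no
    interior stationary point, for which t_extremum = 0 and
    g_extremum = G(0).  Undefined features are ``None``.
    """

    test: str
    g_init: float  # G(0), mmol/L
    g_rate_init: float  # G'(0), mmol/L/min
    g_extremum: float  # mmol/L
    t_extremum: float  # min
    g_rate_I: Optional[float]  # mmol/L/min
    t_I: Optional[float]  # min
    g_stab: float  # G0, mmol/L
    period_h: Optional[float]  # hours
    auc_model: float  # mmol*min/L
    horizon: float  # min
    extremum_at_boundary: bool = False


def _scan_first_root(f, lo: float, hi: float, step: float = _SCAN_STEP_MIN):
    """First sign-change root of ``f`` in (lo, hi], or None.

    Scans on a uniform grid then refines with Brent's method.  An exact
    grid zero is returned as-is.
    """
    grid = np.arange(lo, hi + step, step)
    grid[-1] = min(grid[-1], hi)
    vals = np.asarray(f(grid))  # derivatives are vectorized
    if np.all(vals == 0.0):  # identically-zero derivative (constant curve)
        return None
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if a == 0.0 and grid[i] > lo:
            return float(grid[i])
        if a * b < 0.0:
            return float(brentq(f, grid[i], grid[i + 1], xtol=_ROOT_XTOL_MIN))
    if vals[-1] == 0.0:
        return float(grid[-1])
    return None


def extract_features(
    params: ModelParameters, test: str, horizon: Optional[float] = None
) -> CurveFeatures:
    """Extract the derived curve characteristics for one fitted curve.

    Parameters
    ----------
    params : ModelParameters
        Fitted curve parameters.
    test : {"GTT", "ITT"}
        Selects the sign convention: GTT curves peak (maximum, then the
        steepest decline at t_I); ITT curves dip (minimum, then the
        steepest recovery at t_I).
    horizon : float, optional
        End of the test window in minutes; defaults to 240 (GTT) or
        180 (ITT), the protocol ends.
    """
    test = test.upper()
    if test not in ("GTT", "ITT"):
        raise ValueError(f"test must be 'GTT' or 'ITT', got {test!r}")
    if horizon is None:
        horizon = GTT_HORIZON_MIN if test == "GTT" else ITT_HORIZON_MIN
    if horizon <= 0:
        raise ValueError("horizon must be positive")

    want_max = test == "GTT"
    d1 = lambda t: derivative(params, t, 1)
    d2 = lambda t: derivative(params, t, 2)

    # first interior stationary point with curvature of the expected sign
    t_ext = None
    lo = 0.0
    while True:
        root = _scan_first_root(d1, lo, horizon)
        if root is None:
            break
        curv = d2(root)
        if (want_max and curv < 0) or (not want_max and curv > 0):
            t_ext = root
            break
        lo = root + _SCAN_STEP_MIN  # saddle or wrong-sign extremum: keep looking
        if lo >= horizon:
            break

    boundary = t_ext is None
    if boundary:
        t_ext = 0.0
        g_ext = float(params.mu)
    else:
        g_ext = float(evaluate(params, t_ext))

    # first inflection after the extremum: steepest decline (GTT) / recovery (ITT)
    t_i = _scan_first_root(d2, t_ext, horizon)
    g_rate_i = float(d1(t_i)) if t_i is not None else None

    return CurveFeatures(
        test=test,
        g_init=float(params.mu),
        g_rate_init=float(params.nu),
        g_extremum=g_ext,
        t_extremum=float(t_ext),
        g_rate_I=g_rate_i,
        t_I=float(t_i) if t_i is not None else None,
        g_stab=float(params.g_stab),
        period_h=period(params),
        auc_model=model_auc(params, horizon),
        horizon=float(horizon),
        extremum_at_boundary=boundary,
    )


def _auc_analytic(params: ModelParameters, t0: float, t1: float) -> float:
    """Exact integral of G over [t0, t1] from the branch antiderivative."""
    info = classify_regime(params)
    c1, c2 = _coefficients(params, info)
    a = params.alpha

    if info.regime is Regime.OVERDAMPED:
        r1, r2 = info.r1, info.r2

        def F(t):
            return (
                params.g_stab * t
                + c1 / r1 * np.exp(r1 * t)
                + c2 / r2 * np.exp(r2 * t)
            )

    elif info.regime is Regime.UNDERDAMPED:
        w = info.omega
        den = a**2 + w**2
        if a == 0.0:

            def F(t):
                return params.g_stab * t + (c1 * np.sin(w * t) - c2 * np.cos(w * t)) / w

        else:

            def F(t):
                e = np.exp(-a * t)
                cos, sin = np.cos(w * t), np.sin(w * t)
                # int e^{-at} cos = e^{-at}(w sin - a cos)/(a^2+w^2), etc.
                ic = e * (w * sin - a * cos) / den
                is_ = -e * (w * cos + a * sin) / den
                return params.g_stab * t + c1 * ic + c2 * is_

    else:

        def F(t):
            e = np.exp(-a * t)
            # int (c1 + c2 t) e^{-at} dt
            return params.g_stab * t - e * ((c1 + c2 * t) / a + c2 / a**2)

    return float(F(t1) - F(t0))


def model_auc(
    params: ModelParameters,
    horizon: float,
    start: float = 0.0,
    check: bool = True,
) -> float:
    """Area under the modelled curve, mmol*min/L, over [start, horizon].

    Computed from the closed-form antiderivative of the active solution
    branch; when ``check`` is on the value is cross-validated against
    adaptive quadrature of :func:`evaluate` (the analytic value is always
    the one returned).
    """
    if horizon <= start:
        raise ValueError("horizon must exceed start")
    val = _auc_analytic(params, start, horizon)
    if check:
        ref, _ = quad(lambda t: evaluate(params, t), start, horizon, limit=200)
        scale = max(abs(ref), 1.0)
        if abs(val - ref) > 1e-6 * scale:
            raise FloatingPointError(
                f"analytic AUC {val} disagrees with quadrature {ref}"
            )
    return val
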