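"""Classical tolerance-test analysis: trapezoidal AUC and rank tests.

The conventional readout of a tolerance test is the area under the raw
glucose curve (trapezoidal rule on the measured points), compared between
animal groups with the Mann–Whitney U test under Bonferroni correction at
alpha = 0.05; Shapiro–Wilk normality screening is advisory only — the
comparison is nonparametric regardless.  A small glycemic-band classifier
implements the normoglycemia convention used for rats: 4.2–5.5 mmol/L is
normoglycemia, below 2.2 mmol/L severe (life-threatening) hypoglycemia.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .fitting import TimeSeries

__all__ = [
    "GroupComparison",
    "trapezoid_auc",
    "shapiro_normality",
    "compare_groups",
    "classify_glycemia",
    "DEFAULT_CONTRASTS",
    "NORMO_RANGE",
    "SEVERE_HYPO_THRESHOLD",
]

NORMO_RANGE = (4.2, 5.5)  # mmol/L, inclusive
SEVERE_HYPO_THRESHOLD = 2.2  # mmol/L

#: within-sex, across-age contrasts (the study's comparison set)
DEFAULT_CONTRASTS = (
    ("young_male", "adult_male"),
    ("young_female", "adult_female"),
)


@dataclass(frozen=True)
class GroupComparison:
    """One pairwise rank-sum comparison of group AUC samples."""

    group_a: str
    group_b: str
    statistic: float  # Mann-Whitney U for group_a
    p_raw: float
    p_adjusted: float  # Bonferroni: min(1, k * p_raw)
    significant: bool  # p_adjusted < alpha


def trapezoid_auc(series: TimeSeries) -> float:
    """Area under the measured curve by the trapezoidal rule, mmol*min/L.

    Exact for piecewise-linear curves on any grid; computed over the full
    set of measured points.
    """
    if len(np.unique(series.times)) != len(series.times):
        raise ValueError("duplicated time points")
    return float(np.trapezoid(series.glucose, series.times))


def shapiro_normality(values: Sequence[float]) -> Optional[dict]:
    """Shapiro–Wilk W and p for a sample of AUCs; advisory screening only.

    Returns ``None`` for n < 3 or a zero-variance (degenerate) sample,
    where the statistic is undefined.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3 or np.ptp(x) == 0.0:
        return None
    w, p = stats.shapiro(x)
    return {"W": float(w), "p": float(p)}


def _mann_whitney(a: np.ndarray, b: np.ndarray) -> tuple:
    """Two-sided Mann–Whitney U: exact when small and tie-free, else
    normal approximation with tie correction (mid-ranks)."""
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    aucs: Mapping[str, Sequence[float]],
    comparisons: Sequence[tuple] = DEFAULT_CONTRASTS,
    alpha: float = 0.05,
) -> list:
    """Pairwise Mann–Whitney comparisons with Bonferroni correction.

    ``aucs`` maps group label -> per-animal AUC sample (each n >= 3).
    The Bonferroni factor is the number of requested comparisons; a
    contrast is significant when the adjusted p falls below ``alpha``.
    """
    if not comparisons:
        raise ValueError("comparisons must be non-empty")
    k = len(comparisons)
    out = []
    for ga, gb in comparisons:
        a = np.asarray(aucs[ga], dtype=float)
        b = np.asarray(aucs[gb], dtype=float)
        if len(a) < 3 or len(b) < 3:
            raise ValueError(f"groups need n >= 3: {ga} ({len(a)}), {gb} ({len(b)})")
        u, p = _mann_whitney(a, b)
        p_adj = min(1.0, k * p)
        out.append(
            GroupComparison(
                group_a=ga,
                group_b=gb,
                statistic=u,
                p_raw=p,
                p_adjusted=p_adj,
                significant=p_adj < alpha,
            )
        )
    return out


def classify_glycemia(value: float) -> str:
    """Glycemic band of a glucose reading in mmol/L.

    Bands: ``severe_hypo`` (< 2.2), ``hypo`` ([2.2, 4.2)), ``normo``
    ([4.2, 5.5], boundaries inclusive), ``hyper`` (> 5.5).
    """
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"glucose must be positive and finite, got {value}")
    if value < SEVERE_HYPO_THRESHOLD:
        return "severe_hypo"
    if value < NORMO_RANGE[0]:
        return "hypo"
    if value <= NORMO_RANGE[1]:
        return "normo"
    return "hyper"
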