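"""Distributional inference on per-cell features.

Per-cell spatial features of biofilms (nearest-neighbor distances, cluster
indices) are typically right-skewed and non-normal, so the comparison
battery is: Shapiro-Wilk normality, a moment-based skewness significance
test, medians, and the Mann-Whitney U test for a two-sample median
comparison.  All tests are two-sided with alpha = 0.05 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "FeatureSample",
    "shapiro_wilk",
    "skewness_test",
    "mann_whitney",
    "feature_summary",
]


@dataclass(frozen=True)
class FeatureSample:
    """A named sample of one per-cell feature (um or 1/um)."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if np.isnan(v).any():
            raise ValueError("feature sample contains NaN")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.values)


def _as_sample(s) -> FeatureSample:
    return s if isinstance(s, FeatureSample) else FeatureSample(np.asarray(s))


def shapiro_wilk(s: FeatureSample) -> tuple[float, float]:
    """Shapiro-Wilk W and its p-value (3 <= n <= 5000)."""
    s = _as_sample(s)
    if not 3 <= s.n <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {s.n}")
    if np.ptp(s.values) == 0:
        raise ValueError("zero variance: normality test undefined")
    w, p = stats.shapiro(s.values)
    return float(w), float(p)


def skewness_test(s: FeatureSample, alpha: float = 0.05
                  ) -> tuple[float, float, float, str]:
    """Moment skewness g1 = m3/m2^1.5 with its large-sample z test.

    SE(g1) = sqrt(6 n (n-1) / ((n-2)(n+1)(n+3))); two-sided p; the verdict
    is "Yes" (significantly skewed) when p <= alpha.  Requires n >= 8.
    Returns ``(g1, z, p, verdict)``.
    """
    s = _as_sample(s)
    if s.n < 8:
        raise ValueError(f"skewness test requires n >= 8, got {s.n}")
    v = s.values
    m2 = np.mean((v - v.mean()) ** 2)
    if m2 == 0:
        raise ValueError("zero variance: skewness undefined")
    m3 = np.mean((v - v.mean()) ** 3)
    g1 = m3 / m2 ** 1.5
    n = s.n
    se = np.sqrt(6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3)))
    z = g1 / se
    p = 2 * stats.norm.sf(abs(z))
    verdict = "Yes" if p <= alpha else "No"
    return float(g1), float(z), float(p), verdict


def mann_whitney(a: FeatureSample, b: FeatureSample
                 ) -> tuple[float, float, str]:
    """Mann-Whitney U test for a difference in medians.

    Midrank tie handling with the tie-corrected normal approximation
    (exact enumeration for small tie-free samples).  Returns the smaller of
    the two U statistics, the two-sided p-value, and the label of the
    sample with the larger median (e.g. "CS25 > CS4"); equal medians yield
    an "=" relation.
    """
    a, b = _as_sample(a), _as_sample(b)
    if a.n < 3 or b.n < 3:
        raise ValueError("both samples need n >= 3")
    res = stats.mannwhitneyu(a.values, b.values, alternative="two-sided")
    u1 = float(res.statistic)
    u = min(u1, a.n * b.n - u1)
    med_a, med_b = np.median(a.values), np.median(b.values)
    la = a.label or "a"
    lb = b.label or "b"
    if med_a > med_b:
        direction = f"{la} > {lb}"
    elif med_b > med_a:
        direction = f"{lb} > {la}"
    else:
        direction = f"{la} = {lb}"
    return u, float(res.pvalue), direction


def feature_summary(s: FeatureSample, alpha: float = 0.05) -> dict:
    """One row of the inference table for a single feature sample."""
    s = _as_sample(s)
    w, p_w = shapiro_wilk(s)
    g1, z, p_s, skewed = skewness_test(s, alpha=alpha)
    return {
        "label": s.label,
        "n": s.n,
        "shapiro_w": w,
        "shapiro_p": p_w,
        "normal": "No" if p_w <= alpha else "Yes",
        "skewness_g1": g1,
        "skewness_z": z,
        "skewness_p": p_s,
        "significantly_skewed": skewed,
        "median": float(np.median(s.values)),
    }
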