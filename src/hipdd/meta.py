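"""Fixed-effects meta-analysis of municipality-specific relative effects.

Each treated municipality contributes a log incidence-rate ratio
``theta_i`` with standard error ``se_i``.  Inverse-variance pooling with
weights ``w_i = 1/se_i^2`` gives the common-effect summary

    theta_hat = sum(w_i * theta_i) / sum(w_i),   SE = 1 / sqrt(sum(w_i)),

and Cochran's Q = ``sum w_i (theta_i - theta_hat)^2`` tests effect
homogeneity against a chi-square law with k - 1 degrees of freedom.
The pooled log-IRR back-transforms to a percent change for reporting
(e.g. a pooled IRR of 0.89 reads as an 11% relative reduction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MetaResult", "MetaError", "fixed_effect_pool", "q_test",
           "chi2_upper_tail", "meta_analyse"]


class MetaError(ValueError):
    """Meta-analysis preconditions violated."""


@dataclass(frozen=True)
class MetaResult:
    """Pooled relative effect, heterogeneity test and per-unit weights."""

    pooled_log_irr: float
    pooled_se: float
    pooled_irr: float
    pooled_ci: tuple[float, float]  # on the IRR scale
    q: float
    df: int
    p_value: float
    weights: np.ndarray  # w_i = 1/se_i^2
    estimates: np.ndarray  # the per-unit log-IRRs echoed
    ses: np.ndarray
    labels: tuple

    def to_frame(self) -> pd.DataFrame:
        """Forest-table layout: one row per unit plus a summary row."""
        z = stats.norm.ppf(0.975)
        rows = pd.DataFrame({
            "unit": list(self.labels),
            "irr": np.exp(self.estimates),
            "irr_lo": np.exp(self.estimates - z * self.ses),
            "irr_hi": np.exp(self.estimates + z * self.ses),
            "weight_pct": 100 * self.weights / self.weights.sum(),
        })
        summary = pd.DataFrame({
            "unit": ["pooled (fixed effects)"],
            "irr": [self.pooled_irr],
            "irr_lo": [self.pooled_ci[0]],
            "irr_hi": [self.pooled_ci[1]],
            "weight_pct": [100.0],
        })
        return pd.concat([rows, summary], ignore_index=True)


def _validate(estimates, ses, k_min: int):
    theta = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if theta.shape != se.shape or theta.ndim != 1:
        raise MetaError("estimates and ses must be 1-d arrays of equal length")
    if len(theta) < k_min:
        raise MetaError(f"need at least {k_min} estimates")
    if not np.all(np.isfinite(theta)) or not np.all(np.isfinite(se)):
        raise MetaError("estimates and ses must be finite")
    if np.any(se <= 0):
        raise MetaError("standard errors must be strictly positive")
    return theta, se


def fixed_effect_pool(
    estimates, ses, level: float = 0.95
) -> tuple[float, float, tuple[float, float]]:
    """Inverse-variance pooled estimate with a normal interval.

    Returns ``(pooled, se, (lo, hi))`` on the scale of ``estimates``.
    """
    theta, se = _validate(estimates, ses, k_min=1)
    w = 1.0 / se**2
    pooled = float(np.sum(w * theta) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    z = stats.norm.ppf(0.5 + level / 2)
    return pooled, pooled_se, (pooled - z * pooled_se, pooled + z * pooled_se)


def q_test(estimates, ses) -> tuple[float, int, float]:
    """Cochran's Q homogeneity test: (Q, df, upper-tail p)."""
    theta, se = _validate(estimates, ses, k_min=2)
    pooled, _, _ = fixed_effect_pool(theta, se)
    w = 1.0 / se**2
    q = float(np.sum(w * (theta - pooled) ** 2))
    df = len(theta) - 1
    return q, df, chi2_upper_tail(q, df)


def chi2_upper_tail(x: float, df: int) -> float:
    """P(X >= x) for a chi-square law with ``df`` degrees of freedom."""
    if df < 1:
        raise MetaError("df must be >= 1")
    if x < 0:
        raise MetaError("x must be non-negative")
    return float(stats.chi2.sf(x, df))


def meta_analyse(estimates, ses, labels=None, level: float = 0.95) -> MetaResult:
    """Full fixed-effects meta-analysis of per-unit log-IRRs."""
    theta, se = _validate(estimates, ses, k_min=2)
    pooled, pooled_se, (lo, hi) = fixed_effect_pool(theta, se, level=level)
    q, df, p = q_test(theta, se)
    if labels is None:
        labels = tuple(range(1, len(theta) + 1))
    return MetaResult(
        pooled_log_irr=pooled,
        pooled_se=pooled_se,
        pooled_irr=float(np.exp(pooled)),
        pooled_ci=(float(np.exp(lo)), float(np.exp(hi))),
        q=q, df=df, p_value=p,
        weights=1.0 / se**2,
        estimates=theta, ses=se, labels=tuple(labels),
    )
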