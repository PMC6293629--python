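"""Difference-in-differences effect measures on a matched incidence panel.

Four effect measures quantify the intervention, all built from the
treated aggregate rate series ``T_t`` and the matched-control series
``C_t`` (the unweighted mean of the chosen donor municipalities), with
pre-period mean gap ``g = mean_pre(T - C)``:

* **DD** — average post-period rate difference net of the pre gap,
  ``mean_post(T - C) - g`` (per 100,000 person-years);
* **dynamic effects** — the same contrast year by year, ``(T_t - C_t) - g``;
* **IRR** — ratio of post/pre rate ratios,
  ``(T_post/T_pre) / (C_post/C_pre)``, with the confidence interval on
  the log scale;
* **CE** — cumulative cases prevented,
  ``sum_post (T_t - C_t - g) * P_t / 1e5`` with ``P_t`` the treated
  person-years.

Uncertainty treats the underlying counts as Poisson: each cell's rate
variance is ``cases / person-years^2`` (scaled to per-100,000), delta
methods propagate to each measure's scale, and the resulting standard
errors are inflated by the square root of a design effect
``DEFF = 1 + (m_bar - 1) * ICC`` estimated from the intra-cluster
correlation of municipality-year rates in the matched sample — the
small-sample analogue of cluster-robust standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EffectEstimate",
    "ClusterAdjustment",
    "EffectsError",
    "dd_estimate",
    "dynamic_effects",
    "irr_estimate",
    "cumulative_effect",
    "poisson_ci",
    "normal_ci",
    "cluster_adjust",
    "estimate_effects",
    "effects_table",
]

_CONTROL_VARIANCES = ("donor-wise", "pooled", "donor-mean")


class EffectsError(ValueError):
    """Effect estimation preconditions violated."""


@dataclass(frozen=True)
class ClusterAdjustment:
    """Design-effect correction for within-municipality correlation."""

    icc: float
    m_bar: float  # mean observations (years) per cluster
    deff: float  # 1 + (m_bar - 1) * icc


@dataclass(frozen=True)
class EffectEstimate:
    """All four effect measures for one analysis, with 95% intervals."""

    dd: float
    dd_ci: tuple[float, float]
    ce: float
    ce_ci: tuple[float, float]
    irr: float
    irr_ci: tuple[float, float]
    log_irr: float
    log_irr_se: float
    dynamic: pd.DataFrame  # year, effect, lo, hi
    se_naive: float  # DD standard error before the design effect
    se_adjusted: float
    p_value: float
    n: int  # donor count
    icc: float
    deff: float
    m_bar: float
    level: float
    age_group: str = ""
    sex: str = ""
    label: str = ""
    notes: tuple[str, ...] = ()


def _check_years(series: pd.Series, years: Sequence[int], what: str) -> np.ndarray:
    missing = [y for y in years if y not in series.index]
    if missing:
        raise EffectsError(f"{what} series missing year(s) {missing}")
    return series.loc[list(years)].to_numpy(dtype=float)


def dd_estimate(
    treated: pd.Series,
    matched: pd.Series,
    pre_years: Sequence[int],
    post_years: Sequence[int],
) -> float:
    """Average post-period rate difference net of the pre-period gap."""
    if len(pre_years) == 0 or len(post_years) == 0:
        raise EffectsError("pre_years and post_years must be non-empty")
    t_pre = _check_years(treated, pre_years, "treated")
    t_post = _check_years(treated, post_years, "treated")
    c_pre = _check_years(matched, pre_years, "matched")
    c_post = _check_years(matched, post_years, "matched")
    return float((t_post.mean() - c_post.mean()) - (t_pre.mean() - c_pre.mean()))


def dynamic_effects(
    treated: pd.Series,
    matched: pd.Series,
    pre_years: Sequence[int],
    post_years: Sequence[int],
) -> pd.Series:
    """Per-post-year rate difference net of the pre-period mean gap."""
    if len(pre_years) == 0 or len(post_years) == 0:
        raise EffectsError("pre_years and post_years must be non-empty")
    gap = (
        _check_years(treated, pre_years, "treated").mean()
        - _check_years(matched, pre_years, "matched").mean()
    )
    t = _check_years(treated, post_years, "treated")
    c = _check_years(matched, post_years, "matched")
    return pd.Series(t - c - gap, index=list(post_years), name="effect")


def cumulative_effect(
    treated: pd.Series,
    matched: pd.Series,
    populations: pd.Series,
    pre_years: Sequence[int],
    post_years: Sequence[int],
) -> float:
    """Cumulative cases prevented over the post period.

    The counterfactual rate each post year is the matched rate plus the
    pre-period mean gap; the difference to the observed treated rate is
    converted to cases with the treated person-years.
    """
    missing = [y for y in post_years if y not in populations.index]
    if missing:
        raise EffectsError(f"populations missing year(s) {missing}")
    d = dynamic_effects(treated, matched, pre_years, post_years)
    pops = populations.loc[list(post_years)].to_numpy(dtype=float)
    return float(np.sum(d.to_numpy() * pops / 1e5))


def poisson_ci(
    point: float,
    cases,
    population,
    level: float = 0.95,
    deff: float = 1.0,
) -> tuple[float, float]:
    """Normal-approximation interval for a rate per 100,000.

    ``cases`` and ``population`` may be scalars or arrays (cells are
    summed); the variance is the Poisson count variance propagated to
    the per-100,000 rate scale and inflated by the design effect.
    """
    c = float(np.sum(cases))
    p = float(np.sum(population))
    if p <= 0:
        raise EffectsError("population must be positive")
    if c == 0:
        warnings.warn("all cells zero: Poisson interval has infinite relative width")
    se = 1e5 * np.sqrt(c) / p * np.sqrt(deff)
    z = stats.norm.ppf(0.5 + level / 2)
    return (point - z * se, point + z * se)


def normal_ci(point: float, se: float, level: float = 0.95) -> tuple[float, float]:
    z = stats.norm.ppf(0.5 + level / 2)
    return (point - z * se, point + z * se)


def cluster_adjust(matched_panel: pd.DataFrame) -> ClusterAdjustment:
    """Design effect from the one-way ANOVA ICC of municipality-year rates.

    ``matched_panel`` holds the municipality-year rows of the matched
    sample (treated units plus donors) with ``municipality_id`` and
    ``rate`` columns.  The intra-cluster correlation is the ANOVA
    estimator ``(MSB - MSW) / (MSB + (m0 - 1) * MSW)`` with the
    unbalanced-design coefficient ``m0``, floored at 0; the design
    effect is ``1 + (m_bar - 1) * ICC``.
    """
    groups = matched_panel.groupby("municipality_id")["rate"]
    k = groups.ngroups
    sizes = groups.size().to_numpy(dtype=float)
    n_total = float(sizes.sum())
    m_bar = n_total / k if k else 0.0
    if k < 2 or (sizes < 2).all():
        warnings.warn("cluster_adjust: fewer than 2 informative clusters; DEFF = 1")
        return ClusterAdjustment(icc=0.0, m_bar=m_bar, deff=1.0)

    y = matched_panel["rate"].to_numpy(dtype=float)
    grand = y.mean()
    means = groups.mean()
    ssb = float((sizes * (means.to_numpy() - grand) ** 2).sum())
    ssw = float(((matched_panel["rate"] - matched_panel["municipality_id"].map(means)) ** 2).sum())
    msb = ssb / (k - 1)
    msw = ssw / (n_total - k)
    m0 = (n_total - float((sizes**2).sum()) / n_total) / (k - 1)
    denom = msb + (m0 - 1.0) * msw
    icc = 0.0 if denom <= 0 else (msb - msw) / denom
    icc = float(min(max(icc, 0.0), 1.0))
    return ClusterAdjustment(icc=icc, m_bar=m_bar, deff=1.0 + (m_bar - 1.0) * icc)


def _period_stats(cases: np.ndarray, pops: np.ndarray):
    """Mean rate over years and variance of that mean (Poisson cells).

    ``cases``/``pops`` are [years] aggregates of one arm; rate variance
    per year is 1e10 * cases / pop^2.
    """
    rates = cases / pops * 1e5
    var = float(np.sum(1e10 * cases / pops**2) / len(cases) ** 2)
    return float(rates.mean()), var


def irr_estimate(
    treated_rates: tuple[float, float],
    matched_rates: tuple[float, float],
    var_log: float,
    deff: float = 1.0,
    level: float = 0.95,
) -> tuple[float, tuple[float, float], float]:
    """Ratio-of-ratios IRR with a log-scale normal interval.

    ``treated_rates``/``matched_rates`` are (pre, post) period mean
    rates; ``var_log`` is the summed delta-method variance of the log
    ratio before the design effect.  Returns (irr, ci, se_log_adjusted).
    """
    (t_pre, t_post), (c_pre, c_post) = treated_rates, matched_rates
    if min(t_pre, t_post, c_pre, c_post) <= 0:
        raise EffectsError("IRR requires positive period rates (apply continuity first)")
    irr = (t_post / t_pre) / (c_post / c_pre)
    se = float(np.sqrt(var_log * deff))
    z = stats.norm.ppf(0.5 + level / 2)
    lo, hi = np.exp(np.log(irr) - z * se), np.exp(np.log(irr) + z * se)
    return float(irr), (float(lo), float(hi)), se


def _arm_arrays(
    panel_slice: pd.DataFrame, ids: Iterable[int], years: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-municipality cases and populations, shape [units, years]."""
    ids = list(ids)
    sub = panel_slice[panel_slice["municipality_id"].isin(set(ids))]
    cases = sub.pivot_table(index="municipality_id", columns="year",
                            values="cases", aggfunc="first")
    pops = sub.pivot_table(index="municipality_id", columns="year",
                           values="population", aggfunc="first")
    missing = [y for y in years if y not in cases.columns]
    if missing:
        raise EffectsError(f"panel slice missing year(s) {missing}")
    return (
        cases.loc[ids, list(years)].to_numpy(dtype=float),
        pops.loc[ids, list(years)].to_numpy(dtype=float),
    )


def _control_var_per_year(c_cases: np.ndarray, c_pops: np.ndarray, how: str) -> np.ndarray:
    """Per-year variance of the matched-control series (per-100k scale).

    donor-wise: exact delta-method variance of the unweighted donor mean;
    pooled:     variance of the donor aggregate rate (sum/sum);
    donor-mean: the donor mean treated as one Poisson count of mean
                magnitude (a deliberately conservative convention).
    """
    n = c_cases.shape[0]
    if how == "donor-wise":
        return np.sum(1e10 * c_cases / c_pops**2, axis=0) / n**2
    if how == "pooled":
        return 1e10 * c_cases.sum(axis=0) / c_pops.sum(axis=0) ** 2
    if how == "donor-mean":
        return 1e10 * c_cases.mean(axis=0) / c_pops.mean(axis=0) ** 2
    raise EffectsError(f"control_variance must be one of {_CONTROL_VARIANCES}")


def estimate_effects(
    panel_slice: pd.DataFrame,
    match_result,
    pre_years: Sequence[int],
    post_years: Sequence[int],
    level: float = 0.95,
    control_variance: str = "donor-wise",
    ce_ci: str = "independent",
    gap_variance: str = "fixed",
    age_group: str = "",
    sex: str = "",
    label: str = "",
) -> EffectEstimate:
    """Compute DD, dynamic, IRR and CE with design-effect-adjusted CIs.

    ``panel_slice`` is one stratum of the incidence panel;
    ``match_result`` supplies the treated ids, donor ids and the two
    series.  ``ce_ci`` selects independent Poisson propagation for the
    cumulative effect (default) or rescaling of the DD interval
    (``"from-dd"``).

    ``gap_variance`` controls whether the pre-period mean gap counts as
    a stochastic term.  The default ``"fixed"`` propagates Poisson
    variance from the post-period cells only: nearest-neighbour
    selection pins the matched series to the treated series over the
    pre-period, so the residual pre gap is strongly anti-correlated
    with the pre-period noise and treating it as an independent term
    double-counts variance the selection already absorbed (the interval
    then over-covers badly).  ``"propagated"`` adds the pre-period cell
    variance of both arms, the conservative four-cell convention.
    The IRR always uses the four-period-cell log-scale variance.
    """
    if control_variance not in _CONTROL_VARIANCES:
        raise EffectsError(f"control_variance must be one of {_CONTROL_VARIANCES}")
    if gap_variance not in ("fixed", "propagated"):
        raise EffectsError("gap_variance must be 'fixed' or 'propagated'")
    pre_years, post_years = list(pre_years), list(post_years)
    notes: list[str] = []

    treated = match_result.treated
    matched = match_result.matched
    t_ids, d_ids = list(match_result.treated_ids), list(match_result.donor_ids)
    all_years = pre_years + post_years

    t_cases_u, t_pops_u = _arm_arrays(panel_slice, t_ids, all_years)
    c_cases, c_pops = _arm_arrays(panel_slice, d_ids, all_years)
    t_cases, t_pops = t_cases_u.sum(axis=0), t_pops_u.sum(axis=0)

    v_t = 1e10 * t_cases / t_pops**2
    v_c = _control_var_per_year(c_cases, c_pops, control_variance)
    n_pre, n_post = len(pre_years), len(post_years)
    pre_ix, post_ix = slice(0, n_pre), slice(n_pre, n_pre + n_post)

    adj = cluster_adjust(
        panel_slice[
            panel_slice["municipality_id"].isin(set(t_ids) | set(d_ids))
            & panel_slice["year"].isin(all_years)
        ]
    )
    z = stats.norm.ppf(0.5 + level / 2)

    # ---- DD -------------------------------------------------------------
    dd = dd_estimate(treated, matched, pre_years, post_years)
    var_gap = (v_t[pre_ix].sum() + v_c[pre_ix].sum()) / n_pre**2
    if gap_variance == "fixed":
        var_gap = 0.0
    var_post = (v_t[post_ix].sum() + v_c[post_ix].sum()) / n_post**2
    se_naive = float(np.sqrt(var_post + var_gap))
    se_adj = se_naive * float(np.sqrt(adj.deff))
    dd_ci = (dd - z * se_adj, dd + z * se_adj)
    p_value = float(2 * stats.norm.sf(abs(dd) / se_adj)) if se_adj > 0 else float(dd == 0)

    # ---- dynamic --------------------------------------------------------
    dyn = dynamic_effects(treated, matched, pre_years, post_years)
    dyn_se = np.sqrt((v_t[post_ix] + v_c[post_ix] + var_gap) * adj.deff)
    dynamic = pd.DataFrame({
        "year": post_years,
        "effect": dyn.to_numpy(),
        "lo": dyn.to_numpy() - z * dyn_se,
        "hi": dyn.to_numpy() + z * dyn_se,
    })

    # ---- IRR ------------------------------------------------------------
    t_pre_rate = float(_check_years(treated, pre_years, "treated").mean())
    t_post_rate = float(_check_years(treated, post_years, "treated").mean())
    c_pre_rate = float(_check_years(matched, pre_years, "matched").mean())
    c_post_rate = float(_check_years(matched, post_years, "matched").mean())
    zero_cell = (
        t_cases[pre_ix].sum() == 0
        or t_cases[post_ix].sum() == 0
        or c_cases[:, pre_ix].sum() == 0
        or c_cases[:, post_ix].sum() == 0
        or min(t_pre_rate, t_post_rate, c_pre_rate, c_post_rate) <= 0
    )
    if zero_cell:
        # Haldane-Anscombe: half a case in every aggregate period cell
        notes.append("zero cell in IRR: added 0.5 to every period cell")
        warnings.warn(notes[-1])
        tp, tq = t_cases[pre_ix].sum() + 0.5, t_cases[post_ix].sum() + 0.5
        cp, cq = c_cases[:, pre_ix].sum() + 0.5, c_cases[:, post_ix].sum() + 0.5
        t_pre_rate = tp / t_pops[pre_ix].sum() * 1e5
        t_post_rate = tq / t_pops[post_ix].sum() * 1e5
        c_pre_rate = cp / c_pops[:, pre_ix].sum() * 1e5
        c_post_rate = cq / c_pops[:, post_ix].sum() * 1e5
        var_log = 1 / tp + 1 / tq + 1 / cp + 1 / cq
    else:
        var_log = (
            (v_t[pre_ix].sum() / n_pre**2) / t_pre_rate**2
            + (v_t[post_ix].sum() / n_post**2) / t_post_rate**2
            + (v_c[pre_ix].sum() / n_pre**2) / c_pre_rate**2
            + (v_c[post_ix].sum() / n_post**2) / c_post_rate**2
        )
    irr, irr_ci, se_log = irr_estimate(
        (t_pre_rate, t_post_rate), (c_pre_rate, c_post_rate),
        var_log, deff=adj.deff, level=level,
    )

    # ---- CE -------------------------------------------------------------
    pop_series = pd.Series(t_pops, index=all_years)
    ce = cumulative_effect(treated, matched, pop_series, pre_years, post_years)
    scale = t_pops[post_ix] / 1e5
    if ce_ci == "from-dd":
        se_ce = se_adj * float(scale.sum())
    else:
        var_ce = (
            float(np.sum(scale**2 * (v_t[post_ix] + v_c[post_ix])))
            + float(scale.sum()) ** 2 * var_gap
        )
        se_ce = float(np.sqrt(var_ce * adj.deff))
    ce_interval = (ce - z * se_ce, ce + z * se_ce)

    return EffectEstimate(
        dd=dd, dd_ci=dd_ci, ce=ce, ce_ci=ce_interval,
        irr=irr, irr_ci=irr_ci,
        log_irr=float(np.log(irr)), log_irr_se=se_log,
        dynamic=dynamic,
        se_naive=se_naive, se_adjusted=se_adj, p_value=p_value,
        n=match_result.n, icc=adj.icc, deff=adj.deff, m_bar=adj.m_bar,
        level=level, age_group=age_group, sex=sex, label=label,
        notes=tuple(notes),
    )


def effects_table(estimates: Iterable[EffectEstimate]) -> pd.DataFrame:
    """Flatten estimates into the standard results-table layout."""
    rows = []
    for e in estimates:
        rows.append({
            "sample": e.label or "treated",
            "age_group": e.age_group,
            "sex": e.sex,
            "dd": e.dd, "dd_lo": e.dd_ci[0], "dd_hi": e.dd_ci[1],
            "ce": e.ce, "ce_lo": e.ce_ci[0], "ce_hi": e.ce_ci[1],
            "irr": e.irr, "irr_lo": e.irr_ci[0], "irr_hi": e.irr_ci[1],
            "p_value": e.p_value, "icc": e.icc, "deff": e.deff, "n": e.n,
        })
    return pd.DataFrame(rows)
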