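"""Nearest-neighbour matching on pre-intervention incidence trends.

Control municipalities are chosen for a treated unit (or for the pooled
treated group) by ranking every candidate on the mean squared
discrepancy of its pre-intervention rate series from the treated series,
then averaging the *k* nearest candidates.  The donor count *k* is not a
free parameter: it is chosen by cross-validation on held-out
pre-intervention years, which guards against matching on sampling noise
rather than on the underlying trend — the chronic failure mode of
synthetic-control style re-weighting on noisy small-area incidence
series.

The matched control series is the unweighted mean of the chosen donors,
so the resulting counterfactual is a transparent average of real
municipalities rather than a re-weighted composite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MatchSpec",
    "MatchResult",
    "MatchError",
    "treated_series",
    "pretrend_distance",
    "rank_controls",
    "cross_validate_k",
    "match",
]

_DISTANCES = ("level-mse", "demeaned-mse", "first-difference-mse")


class MatchError(ValueError):
    """Matching preconditions violated (missing years, no candidates...)."""


@dataclass(frozen=True)
class MatchSpec:
    """How donors are ranked and how many are kept.

    ``validation_years`` default to the last three pre-intervention
    years: the match must forecast the treated series forward, so a
    forward-looking holdout mimics the task it is selected for.
    """

    pre_years: tuple[int, ...]
    validation_years: tuple[int, ...] | None = None
    k_max: int = 50
    distance: str = "level-mse"
    treated_mode: str = "pooled"  # or "single"
    final_rank_years: str = "all-pre"  # or "training"

    def __post_init__(self) -> None:
        if len(self.pre_years) < 3:
            raise MatchError("pre_years: need at least 3 pre-intervention years")
        if self.validation_years is None:
            object.__setattr__(
                self, "validation_years", tuple(sorted(self.pre_years)[-3:])
            )
        if not set(self.validation_years) < set(self.pre_years):
            raise MatchError("validation_years: must be a proper subset of pre_years")
        if len(self.training_years) < 2:
            raise MatchError("validation_years: leave at least 2 training years")
        if self.k_max < 1:
            raise MatchError("k_max: must be >= 1")
        if self.distance not in _DISTANCES:
            raise MatchError(f"distance: must be one of {_DISTANCES}")
        if self.treated_mode not in ("pooled", "single"):
            raise MatchError("treated_mode: must be 'pooled' or 'single'")
        if self.final_rank_years not in ("all-pre", "training"):
            raise MatchError("final_rank_years: must be 'all-pre' or 'training'")

    @property
    def training_years(self) -> tuple[int, ...]:
        return tuple(y for y in sorted(self.pre_years) if y not in set(self.validation_years))


@dataclass(frozen=True)
class MatchResult:
    """Ranked donors, the CV error curve and the matched control series."""

    treated_ids: tuple[int, ...]
    treated: pd.Series  # rate per 100k by year, all study years
    ranking: pd.DataFrame  # municipality_id, distance; ascending
    cv_error: pd.Series  # MSE on validation years, indexed by k
    n: int  # chosen donor count = argmin cv_error (ties -> smallest k)
    donor_ids: tuple[int, ...]
    matched: pd.Series  # unweighted mean of the n nearest donors
    spec: MatchSpec


def treated_series(
    panel_slice: pd.DataFrame, treated_ids: Iterable[int], mode: str = "pooled"
) -> pd.Series:
    """The treated outcome series: aggregate rate of the treated group.

    Pooled mode aggregates counts (sum cases / sum person-years x 1e5),
    i.e. the group's actual incidence rate; single mode requires exactly
    one treated id and returns its own series.
    """
    ids = sorted(set(treated_ids))
    sub = panel_slice[panel_slice["municipality_id"].isin(ids)]
    if sub.empty:
        raise MatchError("no rows for the treated units in this panel slice")
    if mode == "single":
        if len(ids) != 1:
            raise MatchError("treated_mode='single' requires exactly one treated id")
        return sub.set_index("year")["rate"].sort_index()
    g = sub.groupby("year")[["cases", "population"]].sum()
    return (g["cases"] / g["population"] * 1e5).rename("rate")


def _series_on_years(series: pd.Series, years: Sequence[int]) -> np.ndarray:
    missing = [y for y in years if y not in series.index]
    if missing:
        raise MatchError(f"series missing year(s) {missing}")
    return series.loc[list(years)].to_numpy(dtype=float)


def pretrend_distance(
    treated: pd.Series,
    candidate: pd.Series,
    spec: MatchSpec,
    years: Sequence[int] | None = None,
) -> float:
    """Mean squared discrepancy between two rate series on pre-years.

    ``level-mse`` compares the raw series, ``demeaned-mse`` removes each
    series' own mean first (trend-only matching), and
    ``first-difference-mse`` compares year-on-year changes.
    """
    years = list(years if years is not None else sorted(spec.pre_years))
    t = _series_on_years(treated, years)
    c = _series_on_years(candidate, years)
    if spec.distance == "demeaned-mse":
        t, c = t - t.mean(), c - c.mean()
    elif spec.distance == "first-difference-mse":
        if len(years) < 2:
            raise MatchError("first-difference-mse needs >= 2 years")
        t, c = np.diff(t), np.diff(c)
    return float(np.mean((t - c) ** 2))


def _rates_by_municipality(panel_slice: pd.DataFrame) -> pd.DataFrame:
    return panel_slice.pivot_table(
        index="municipality_id", columns="year", values="rate", aggfunc="first"
    )


def rank_controls(
    panel_slice: pd.DataFrame,
    treated_ids: Iterable[int],
    spec: MatchSpec,
    years: Sequence[int] | None = None,
) -> pd.DataFrame:
    """All candidate controls sorted by pre-trend distance.

    Candidates are every untreated municipality in the slice.  Ties in
    distance break toward the smaller municipality id, which keeps the
    ranking deterministic.  Returns columns ``municipality_id, distance``.
    """
    ids = set(treated_ids)
    target = treated_series(panel_slice, ids, mode=spec.treated_mode if len(ids) > 1 else "pooled")
    wide = _rates_by_municipality(panel_slice)
    candidates = [m for m in wide.index if m not in ids]
    if not candidates:
        raise MatchError("no candidate control municipalities")
    years = list(years if years is not None else sorted(spec.pre_years))
    t = _series_on_years(target, years)
    missing = [y for y in years if y not in wide.columns]
    if missing:
        raise MatchError(f"series missing year(s) {missing}")
    c_mat = wide.loc[candidates, years].to_numpy(dtype=float)
    if np.isnan(c_mat).any():
        bad = [m for m, row in zip(candidates, c_mat) if np.isnan(row).any()]
        raise MatchError(f"candidate series with missing years: {bad[:5]}")
    tt, cc = t[None, :], c_mat
    if spec.distance == "demeaned-mse":
        tt = tt - tt.mean(axis=1, keepdims=True)
        cc = cc - cc.mean(axis=1, keepdims=True)
    elif spec.distance == "first-difference-mse":
        if len(years) < 2:
            raise MatchError("first-difference-mse needs >= 2 years")
        tt, cc = np.diff(tt, axis=1), np.diff(cc, axis=1)
    dists = ((cc - tt) ** 2).mean(axis=1)
    out = pd.DataFrame({"municipality_id": candidates, "distance": dists})
    return out.sort_values(
        ["distance", "municipality_id"], kind="stable"
    ).reset_index(drop=True)


def cross_validate_k(
    panel_slice: pd.DataFrame,
    treated_ids: Iterable[int],
    spec: MatchSpec,
) -> tuple[pd.Series, int]:
    """Choose the donor count by held-out pre-intervention prediction.

    Donors are ranked on the training pre-years only; for each
    k = 1..k_max the mean of the k nearest donor series is scored
    against the treated series on the validation years.  Returns the
    MSE curve (indexed by k) and its argmin (ties toward smaller k).
    """
    ranking = rank_controls(panel_slice, treated_ids, spec, years=spec.training_years)
    k_cap = len(ranking)
    if spec.k_max > k_cap:
        warnings.warn(
            f"k_max={spec.k_max} exceeds the {k_cap} available candidates; clipped"
        )
    k_cap = min(spec.k_max, k_cap)

    target = treated_series(panel_slice, treated_ids, mode=spec.treated_mode)
    wide = _rates_by_municipality(panel_slice)
    val_years = sorted(spec.validation_years)
    t_val = _series_on_years(target, val_years)
    donor_mat = np.stack(
        [
            _series_on_years(wide.loc[m], val_years)
            for m in ranking["municipality_id"]
        ]
    )  # [candidates, val_years]
    running = np.cumsum(donor_mat, axis=0) / np.arange(1, len(donor_mat) + 1)[:, None]
    errs = ((running[:k_cap] - t_val[None, :]) ** 2).mean(axis=1)
    curve = pd.Series(errs, index=pd.RangeIndex(1, k_cap + 1, name="k"), name="cv_mse")
    n = int(curve.index[int(np.argmin(curve.to_numpy()))])
    return curve, n


def match(
    panel_slice: pd.DataFrame,
    treated_ids: Iterable[int],
    spec: MatchSpec,
) -> MatchResult:
    """Full matching step: rank donors, cross-validate k, average donors.

    The final donor set re-ranks candidates on all pre-years (the CV
    step saw only the training years), then the matched control series
    is the unweighted mean of the n nearest donors over every study
    year.
    """
    ids = tuple(sorted(set(treated_ids)))
    cv_curve, n = cross_validate_k(panel_slice, ids, spec)
    final_years = (
        sorted(spec.pre_years)
        if spec.final_rank_years == "all-pre"
        else list(spec.training_years)
    )
    ranking = rank_controls(panel_slice, ids, spec, years=final_years)
    donors = tuple(int(m) for m in ranking["municipality_id"].head(n))
    wide = _rates_by_municipality(panel_slice)
    matched = wide.loc[list(donors)].mean(axis=0)
    matched.name = "rate"
    target = treated_series(panel_slice, ids, mode=spec.treated_mode)
    return MatchResult(
        treated_ids=ids,
        treated=target.sort_index(),
        ranking=ranking,
        cv_error=cv_curve,
        n=n,
        donor_ids=donors,
        matched=matched.sort_index(),
        spec=spec,
    )
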