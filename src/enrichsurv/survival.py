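"""Survival-curve estimation for the whole sample and biomarker-enriched subgroups.

Two estimators are offered. The product-limit (Kaplan-Meier) estimator applied
to the subset of subjects above a biomarker cutoff is the default and the only
one valid for accrual + follow-up designs. The nearest-neighbour estimator
(NNE) smooths conditional survival over biomarker-percentile neighbourhoods
with a box kernel and averages the conditional curves over the eligible
subgroup; it tolerates censoring that depends on the biomarker and yields
subgroup curves that are monotone in time and (up to smoothing error) in the
threshold.

All curves are right-continuous step functions starting at S(0) = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import BiomarkerSurvivalDataset

logger = logging.getLogger("enrichsurv")

__all__ = [
    "SurvivalCurve",
    "DegenerateDataError",
    "ThresholdTooHighError",
    "ExtrapolationError",
    "kaplan_meier",
    "subgroup_curve",
    "survival_at",
    "restricted_mean_observation",
    "biomarker_cutoff",
    "default_span",
]


class DegenerateDataError(ValueError):
    """The data cannot support a survival estimate (e.g. everyone censored at 0)."""


class ThresholdTooHighError(ValueError):
    """The enrichment threshold leaves too few subjects above the cutoff."""


class ExtrapolationError(ValueError):
    """A curve was evaluated beyond the observed follow-up in strict mode."""


@dataclass
class SurvivalCurve:
    """An estimated survival step function with pointwise standard errors.

    ``times`` holds the (strictly increasing) event times at which the curve
    steps down; S(t) = 1 for t before the first step. ``max_time`` is the
    largest observed time (event or censoring) and bounds strict-mode
    evaluation.
    """

    times: np.ndarray
    surv: np.ndarray
    se: np.ndarray
    n_at_risk: np.ndarray
    max_time: float
    method: str = "km"
    subgroup_threshold: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.surv = np.asarray(self.surv, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("curve times must be strictly increasing")
        if np.any(np.diff(self.surv) > 1e-12):
            raise ValueError("survival must be non-increasing")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time": self.times, "surv": self.surv, "se": self.se})


def _product_limit(
    time: np.ndarray, event: np.ndarray, weights: np.ndarray | None = None
):
    """(Optionally weighted) product-limit estimate on observed event times.

    Returns (event_times, surv, greenwood_var, at_risk). Ties between events
    and censorings at the same time are handled the standard way: events are
    taken to precede censorings.
    """
    order = np.argsort(time, kind="stable")
    t = time[order]
    e = event[order]
    w = np.ones_like(t) if weights is None else np.asarray(weights, float)[order]
    ut, first = np.unique(t, return_index=True)
    # weight remaining at risk just before each unique time
    cum_w = np.concatenate([[0.0], np.cumsum(w)])
    total_w = cum_w[-1]
    at_risk = total_w - cum_w[first]
    d = np.add.reduceat(w * e, first)
    has_event = d > 0
    tt = ut[has_event]
    dd = d[has_event]
    rr = at_risk[has_event]
    frac = dd / rr
    surv = np.cumprod(1.0 - frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = np.where(rr > dd, dd / (rr * (rr - dd)), np.inf)
        var = surv**2 * np.cumsum(gw_terms)
    var = np.where(surv == 0.0, 0.0, var)  # Greenwood is 0*inf at S=0
    return tt, surv, var, rr


def kaplan_meier(dataset: BiomarkerSurvivalDataset) -> SurvivalCurve:
    """Product-limit survival estimate with Greenwood standard errors."""
    if dataset.n == 0:
        raise DegenerateDataError("empty dataset")
    if np.all((dataset.time == 0) & (dataset.event == 0)):
        raise DegenerateDataError("all subjects censored at time 0")
    tt, surv, var, rr = _product_limit(dataset.time, dataset.event)
    return SurvivalCurve(
        times=tt,
        surv=surv,
        se=np.sqrt(var),
        n_at_risk=rr,
        max_time=float(dataset.time.max()),
        method="km",
        subgroup_threshold=0.0,
    )


def biomarker_cutoff(biomarker: np.ndarray, threshold: float) -> float:
    """Nearest-rank empirical quantile used as the eligibility cutoff.

    Eligibility is ``biomarker >= cutoff`` so ties at the cutoff are included.
    ``threshold`` is the fraction of the sample screened out; 0 means no
    enrichment (cutoff at -inf).
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must lie in [0, 1)")
    if threshold == 0.0:
        return -np.inf
    xs = np.sort(np.asarray(biomarker, float))
    k = int(np.ceil(threshold * len(xs))) - 1
    return float(xs[k])


def default_span(n: int) -> float:
    """Default NNE percentile half-width: 0.25 * n**-0.2."""
    return 0.25 * n ** (-0.20)


def subgroup_curve(
    dataset: BiomarkerSurvivalDataset,
    threshold: float,
    method: str = "km",
    span: float | None = None,
) -> SurvivalCurve:
    """Survival curve for the subgroup above the threshold biomarker quantile.

    ``method="km"`` fits the product-limit estimator on the eligible subset.
    ``method="nne"`` averages kernel-smoothed conditional survival curves
    S(t | X = x_i) over eligible subjects, i.e. estimates
    P(T > t, X >= cutoff) / P(X >= cutoff); its standard errors are
    approximated by the Greenwood errors of the subgroup product-limit fit.
    """
    cutoff = biomarker_cutoff(dataset.biomarker, threshold)
    mask = dataset.biomarker >= cutoff
    m = int(mask.sum())
    if m == 0:
        raise ThresholdTooHighError(f"no subjects above cutoff for threshold {threshold}")
    if m < 10:
        raise ThresholdTooHighError(
            f"threshold {threshold} leaves only {m} subjects above the cutoff "
            "(minimum 10)"
        )
    if method == "km":
        curve = kaplan_meier(dataset.subset(mask))
        curve.subgroup_threshold = threshold
        return curve
    if method != "nne":
        raise ValueError(f"unknown estimator {method!r}")
    return _nne_curve(dataset, threshold, mask, span)


def _nne_curve(
    dataset: BiomarkerSurvivalDataset,
    threshold: float,
    mask: np.ndarray,
    span: float | None,
) -> SurvivalCurve:
    n = dataset.n
    if span is None:
        span = default_span(n)
    if span <= 0:
        raise ValueError("span must be positive")
    order = np.argsort(dataset.biomarker, kind="stable")
    t_by_x = dataset.time[order]
    e_by_x = dataset.event[order]
    pct = (np.arange(n) + 0.5) / n  # biomarker percentile of each sorted subject
    elig_sorted = mask[order]

    grid = np.unique(dataset.time[dataset.event == 1])
    if grid.size == 0:
        raise DegenerateDataError("no events observed; NNE curve undefined")

    acc = np.zeros(grid.size)
    cache: dict[tuple[int, int], np.ndarray] = {}
    for i in np.flatnonzero(elig_sorted):
        lo = int(np.searchsorted(pct, pct[i] - span, side="left"))
        hi = int(np.searchsorted(pct, pct[i] + span, side="right"))
        key = (lo, hi)
        cond = cache.get(key)
        if cond is None:
            tt, surv, _, _ = _product_limit(t_by_x[lo:hi], e_by_x[lo:hi])
            idx = np.searchsorted(tt, grid, side="right")
            cond = np.where(idx == 0, 1.0, surv[np.maximum(idx - 1, 0)])
            cache[key] = cond
        acc += cond
    smoothed = acc / elig_sorted.sum()
    smoothed = np.minimum.accumulate(smoothed)  # guard tiny non-monotone wiggles

    # keep only times where the averaged curve actually steps
    keep = np.concatenate([[True], np.diff(smoothed) < 0])
    km_sub = kaplan_meier(dataset.subset(mask))
    j = np.searchsorted(km_sub.times, grid[keep], side="right")
    se = np.where(j == 0, 0.0, km_sub.se[np.maximum(j - 1, 0)])
    idx = np.searchsorted(np.sort(dataset.time[mask]), grid[keep], side="left")
    at_risk = mask.sum() - idx
    return SurvivalCurve(
        times=grid[keep],
        surv=smoothed[keep],
        se=se,
        n_at_risk=at_risk,
        max_time=float(dataset.time[mask].max()),
        method="nne",
        subgroup_threshold=threshold,
    )


def survival_at(
    curve: SurvivalCurve, t: float, strict: bool = True
) -> tuple[float, float]:
    """Evaluate the step curve (and its SE) at time ``t``, right-continuously.

    Beyond the last observed time, strict mode raises; lenient mode carries the
    last value forward with a logged warning.
    """
    if t < 0:
        raise ValueError("time must be non-negative")
    if t > curve.max_time:
        if strict:
            raise ExtrapolationError(
                f"t = {t} exceeds the observed follow-up ({curve.max_time}); "
                "use strict=False to carry the last value forward"
            )
        logger.warning(
            "evaluating survival curve at t=%s beyond follow-up %s; "
            "carrying last value forward",
            t,
            curve.max_time,
        )
    i = int(np.searchsorted(curve.times, t, side="right"))
    if i == 0:
        return 1.0, 0.0
    return float(curve.surv[i - 1]), float(curve.se[i - 1])


def restricted_mean_observation(
    curve: SurvivalCurve, horizon: float, strict: bool = True, hazard_power: float = 1.0
) -> float:
    """Area under the survival step curve on [0, horizon].

    This is the expected time free of the endpoint within the horizon
    (restricted mean), used for time-dependent per-patient trial cost.
    ``hazard_power`` integrates S(t)**hr instead, giving the treatment-arm
    restricted mean under a proportional-hazards effect.
    """
    if horizon < 0:
        raise ValueError("horizon must be non-negative")
    if horizon == 0:
        return 0.0
    if strict and horizon > curve.max_time:
        raise ExtrapolationError(
            f"horizon {horizon} exceeds the observed follow-up ({curve.max_time})"
        )
    knots = np.concatenate([[0.0], curve.times])
    values = np.concatenate([[1.0], curve.surv]) ** hazard_power
    ends = np.minimum(np.append(knots[1:], np.inf), horizon)
    starts = np.minimum(knots, horizon)
    return float(np.sum(values * np.clip(ends - starts, 0.0, None)))
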