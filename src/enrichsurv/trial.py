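"""Trial design quantities: required events, event rates, sample size, cost.

The chain implemented here, per enrichment threshold, is:

    required events  N0 = 4 (z_{1-a/2} + z_{1-b})^2 / log^2 HR
    event rates      pC = 1 - S,  pT = 1 - S^HR           (fixed duration)
                     Simpson-weighted versions of the same (accrual design)
    sample size      N = 2 N0 / (pC + pT)
    patients screened  N / (1 - t)     for enrichment threshold t
    total cost       C1 * N + C2 * N / (1 - t)   (or time-based per-patient cost)

N0 comes from the standard log-rank events formula and is treated as fixed;
sampling variability enters only through the estimated survival S. For fixed
durations, SD(p) and SD(N) follow by the delta method; accrual designs use the
nonparametric bootstrap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .io import BiomarkerSurvivalDataset
from .survival import (
    SurvivalCurve,
    ThresholdTooHighError,
    subgroup_curve,
    survival_at,
)

logger = logging.getLogger("enrichsurv")

__all__ = [
    "TestingSpec",
    "TrialDesign",
    "EventRateEstimate",
    "CostSpec",
    "SampleSizeResult",
    "InfeasibleDesignError",
    "events_required",
    "event_rates_fixed",
    "event_rates_accrual",
    "sample_size",
    "total_screened",
    "total_cost",
    "cost_reduction",
    "bootstrap_se",
]

SIMPSON_WEIGHTS = np.array([1.0, 4.0, 1.0]) / 6.0


class InfeasibleDesignError(ValueError):
    """The design cannot be powered (HR = 1, or zero event rate)."""


@dataclass(frozen=True)
class TestingSpec:
    """Statistical testing specification: two-sided alpha, power, treatment HR."""

    alpha: float = 0.05
    power: float = 0.90
    treatment_hr: float = 0.8

    def __post_init__(self):
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.treatment_hr <= 0:
            raise ValueError("treatment_hr must be positive")


@dataclass(frozen=True)
class TrialDesign:
    """Fixed-duration (all patients observed T) or accrual(a) + follow-up(f) design."""

    kind: str
    duration: float | None = None
    accrual_time: float | None = None
    followup_time: float | None = None

    @classmethod
    def fixed(cls, duration: float) -> "TrialDesign":
        if duration <= 0:
            raise ValueError("duration must be positive")
        return cls(kind="fixed", duration=duration)

    @classmethod
    def accrual(cls, accrual_time: float, followup_time: float) -> "TrialDesign":
        if accrual_time <= 0 or followup_time <= 0:
            raise ValueError("accrual and follow-up times must be positive")
        return cls(kind="accrual", accrual_time=accrual_time, followup_time=followup_time)

    @property
    def max_observation(self) -> float:
        if self.kind == "fixed":
            return self.duration
        return self.followup_time + self.accrual_time


@dataclass
class EventRateEstimate:
    """Control/treatment event probabilities by end of observation, with SD of their sum."""

    p_control: float
    p_treatment: float
    sd_p: float = np.nan

    @property
    def p_sum(self) -> float:
        return self.p_control + self.p_treatment


@dataclass(frozen=True)
class CostSpec:
    """Screening cost per evaluated patient plus one of two per-patient trial costs.

    Exactly one of ``trial_cost`` (constant per enrolled patient) and
    ``cost_per_time`` (rate per unit time in the trial before the endpoint)
    must be given.
    """

    screening_cost: float
    trial_cost: float | None = None
    cost_per_time: float | None = None

    def __post_init__(self):
        if (self.trial_cost is None) == (self.cost_per_time is None):
            raise ValueError("specify exactly one of trial_cost and cost_per_time")
        for v in (self.screening_cost, self.trial_cost, self.cost_per_time):
            if v is not None and v < 0:
                raise ValueError("costs must be non-negative")


@dataclass
class SampleSizeResult:
    required_events: float
    total_n: float
    sd_n: float = np.nan


def events_required(spec: TestingSpec) -> float:
    """Total events for a log-rank test: 4 (z_{1-a/2} + z_{1-b})^2 / log^2 HR."""
    if spec.treatment_hr == 1:
        raise InfeasibleDesignError("treatment hazard ratio 1 cannot be powered")
    z = norm.ppf(1 - spec.alpha / 2) + norm.ppf(spec.power)
    return float(4 * z**2 / np.log(spec.treatment_hr) ** 2)


def event_rates_fixed(
    s_hat: float, sd_s: float, treatment_hr: float
) -> EventRateEstimate:
    """Arm-specific event rates for a fixed-duration trial from S(T).

    pC = 1 - S, pT = 1 - S^HR; SD(pC + pT) = (1 + HR * S^(HR-1)) * SD(S) by the
    delta method. At S = 0 with HR < 1 the delta slope diverges; the rates are
    still returned but the SD is flagged unreliable (NaN).
    """
    if not 0 <= s_hat <= 1:
        raise ValueError("s_hat must lie in [0, 1]")
    p_control = 1.0 - s_hat
    p_treatment = 1.0 - s_hat**treatment_hr
    if s_hat == 0 and treatment_hr < 1:
        logger.warning("S(T) = 0: delta-method SD is undefined; flagging as NaN")
        return EventRateEstimate(p_control, p_treatment, np.nan)
    sd_p = (1.0 + treatment_hr * s_hat ** (treatment_hr - 1.0)) * sd_s
    return EventRateEstimate(p_control, p_treatment, float(sd_p))


def event_rates_accrual(
    curve: SurvivalCurve,
    accrual_time: float,
    followup_time: float,
    treatment_hr: float,
    strict: bool = True,
) -> EventRateEstimate:
    """Simpson's-rule event rates when observation spans [f, f+a].

    With uniform entry over the accrual period, the average event probability
    is approximated by Simpson's rule over the three follow-up lengths f,
    f + a/2, f + a:  pC = 1 - [S(f) + 4 S(f+a/2) + S(f+a)] / 6, and pT the
    same with each survival raised to the treatment HR. The SD of the rate sum
    is left NaN here; accrual designs estimate it by bootstrap.
    """
    f, a = followup_time, accrual_time
    s = np.array([survival_at(curve, q, strict=strict)[0] for q in (f, f + a / 2, f + a)])
    p_control = 1.0 - float(SIMPSON_WEIGHTS @ s)
    p_treatment = 1.0 - float(SIMPSON_WEIGHTS @ s**treatment_hr)
    # snap floating residue from the weighted sum (e.g. S identically 1)
    if abs(p_control) < 1e-12:
        p_control = 0.0
    if abs(p_treatment) < 1e-12:
        p_treatment = 0.0
    return EventRateEstimate(p_control, p_treatment, np.nan)


def sample_size(n0: float, rates: EventRateEstimate) -> SampleSizeResult:
    """Total sample size N = 2 N0 / (pC + pT), with SD(N) = (2 N0 / p^2) SD(p)."""
    p = rates.p_sum
    if p <= 0:
        raise InfeasibleDesignError("zero event rate implies an infinite trial")
    total_n = 2.0 * n0 / p
    sd_n = (2.0 * n0 / p**2) * rates.sd_p if np.isfinite(rates.sd_p) else np.nan
    return SampleSizeResult(required_events=n0, total_n=total_n, sd_n=sd_n)


def total_screened(total_n: float, threshold: float) -> float:
    """Expected number screened to enroll N at enrichment threshold t: N / (1-t)."""
    if not 0 <= threshold < 1:
        raise ValueError("threshold must lie in [0, 1)")
    return total_n / (1.0 - threshold)


def total_cost(
    total_n: float,
    threshold: float,
    costs: CostSpec,
    expected_time_in_trial: float | None = None,
) -> float:
    """Total trial cost: per-patient trial cost * N + screening cost * N/(1-t)."""
    screened = total_screened(total_n, threshold)
    if costs.trial_cost is not None:
        per_patient = costs.trial_cost
    else:
        if expected_time_in_trial is None:
            raise ValueError(
                "time-based trial cost requires expected_time_in_trial "
                "(restricted mean observation time)"
            )
        per_patient = costs.cost_per_time * expected_time_in_trial
    return per_patient * total_n + costs.screening_cost * screened


def cost_reduction(cost_enriched: float, cost_unenriched: float) -> float:
    """Percent cost saving vs the unenriched trial; negative = enrichment costs more."""
    if cost_unenriched <= 0:
        raise ValueError("unenriched cost must be positive")
    return 100.0 * (1.0 - cost_enriched / cost_unenriched)


def _replicate_statistics(
    dataset: BiomarkerSurvivalDataset,
    design: TrialDesign,
    spec: TestingSpec,
    threshold: float,
    B: int,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Bootstrap replicates of (pC, pC+pT, N) at one threshold.

    Each replicate resamples subjects with replacement and re-derives the
    cutoff, subgroup and curve. Replicates with an empty subgroup or no events
    are skipped (logged); more than 10% skipped is an error.
    """
    n0 = events_required(spec)
    n = dataset.n
    p_control, p_sum, total_n = [], [], []
    skipped = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        boot = BiomarkerSurvivalDataset(
            dataset.biomarker[idx], dataset.time[idx], dataset.event[idx]
        )
        try:
            curve = subgroup_curve(boot, threshold, method="km")
        except (ThresholdTooHighError, ValueError):
            skipped += 1
            continue
        if design.kind == "fixed":
            s, _ = survival_at(curve, design.duration, strict=False)
            rates = event_rates_fixed(s, 0.0, spec.treatment_hr)
        else:
            rates = event_rates_accrual(
                curve,
                design.accrual_time,
                design.followup_time,
                spec.treatment_hr,
                strict=False,
            )
        p_control.append(rates.p_control)
        p_sum.append(rates.p_sum)
        total_n.append(2.0 * n0 / rates.p_sum if rates.p_sum > 0 else np.nan)
    if skipped:
        logger.warning("bootstrap: skipped %d of %d resamples", skipped, B)
        if skipped > 0.10 * B:
            raise RuntimeError(
                f"bootstrap unstable: {skipped}/{B} resamples had an empty subgroup"
            )
    return {
        "event_rate": np.asarray(p_control),
        "p_sum": np.asarray(p_sum),
        "sample_size": np.asarray(total_n),
    }


def bootstrap_se(
    dataset: BiomarkerSurvivalDataset,
    design: TrialDesign,
    spec: TestingSpec,
    threshold: float,
    statistic: str = "event_rate",
    B: int = 200,
    seed: int = 0,
) -> float:
    """Nonparametric bootstrap SE of a per-threshold trial statistic.

    ``statistic`` is ``"event_rate"`` (control-arm event probability) or
    ``"sample_size"`` (total N). Seeded and reproducible.
    """
    if B < 50:
        raise ValueError("use at least 50 bootstrap replicates")
    if statistic not in ("event_rate", "sample_size"):
        raise ValueError(f"unknown statistic {statistic!r}")
    rng = np.random.default_rng(seed)
    reps = _replicate_statistics(dataset, design, spec, threshold, B, rng)[statistic]
    reps = reps[np.isfinite(reps)]
    if reps.size == 0:
        raise RuntimeError("no usable bootstrap replicates")
    return float(np.std(reps, ddof=1))
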