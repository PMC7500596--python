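"""Orchestration: sweep the enrichment grid and assemble the results table.

``analyze`` is the main entry point: for each threshold on the grid it
estimates the subgroup survival curve, converts it to event rates for the
chosen trial design, derives sample size, screening burden and cost, and
attaches uncertainty (delta method for fixed-duration designs, bootstrap for
accrual designs). ``render_outputs`` writes the CSV / parameter log / figure.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .io import (
    BiomarkerSurvivalDataset,
    ConfigurationError,
    round_half_away,
    write_enrichment_table,
)
from .survival import (
    SurvivalCurve,
    biomarker_cutoff,
    restricted_mean_observation,
    subgroup_curve,
    survival_at,
)
from .trial import (
    SIMPSON_WEIGHTS,
    CostSpec,
    TestingSpec,
    TrialDesign,
    _replicate_statistics,
    cost_reduction,
    event_rates_accrual,
    event_rates_fixed,
    events_required,
    sample_size,
    total_cost,
    total_screened,
)

logger = logging.getLogger("enrichsurv")

__all__ = ["EnrichmentRow", "EnrichmentTable", "analyze", "render_outputs", "default_grid"]

#: Thresholds shown as survival curves in the figure.
CURVE_THRESHOLDS = (0.0, 0.25, 0.50, 0.75)


def default_grid() -> np.ndarray:
    """Enrichment thresholds 0, 0.05, ..., 0.90."""
    return np.round(np.arange(0.0, 0.901, 0.05), 2)


@dataclass
class EnrichmentRow:
    """Trial metrics at one enrichment threshold. Rates are percentages."""

    threshold: float
    biomarker_cutoff: float
    event_rate_pct: float
    event_rate_se: float
    treatment_event_rate_pct: float
    sample_size: float
    sample_size_se: float
    total_screened: float
    total_cost: float
    cost_reduction_pct: float


@dataclass
class EnrichmentTable:
    """Per-threshold results plus the design/specs that produced them."""

    rows: list[EnrichmentRow]
    design: TrialDesign
    testing: TestingSpec
    costs: CostSpec | None
    metadata: dict[str, Any] = field(default_factory=dict)
    curves: dict[float, SurvivalCurve] = field(default_factory=dict)

    def __post_init__(self):
        thr = [r.threshold for r in self.rows]
        if thr and (thr[0] != 0.0 or np.any(np.diff(thr) <= 0)):
            raise ValueError("thresholds must start at 0 and increase strictly")

    def to_frame(self) -> pd.DataFrame:
        """Results as a DataFrame: display-rounded columns plus exact parallels."""
        recs = []
        for r in self.rows:
            recs.append(
                {
                    "threshold": r.threshold,
                    "biomarker_cutoff": r.biomarker_cutoff,
                    "event_rate_pct": round_half_away(r.event_rate_pct),
                    "event_rate_se": r.event_rate_se,
                    "sample_size": round_half_away(r.sample_size),
                    "sample_size_se": r.sample_size_se,
                    "total_screened": round_half_away(r.total_screened),
                    "total_cost": r.total_cost,
                    "cost_reduction_pct": r.cost_reduction_pct,
                    "event_rate_pct_exact": r.event_rate_pct,
                    "sample_size_exact": r.sample_size,
                    "total_screened_exact": r.total_screened,
                    "treatment_event_rate_pct_exact": r.treatment_event_rate_pct,
                }
            )
        return pd.DataFrame.from_records(recs)


def _expected_time_in_trial(
    curve: SurvivalCurve, design: TrialDesign, treatment_hr: float, strict: bool
) -> float:
    """Mean time on study before the endpoint, averaged over arms.

    Fixed design: restricted mean observation to T per arm (control from S,
    treatment from S^HR), equal arm weights. Accrual design: the same at
    follow-up lengths f, f+a/2, f+a combined with Simpson weights, mirroring
    the event-rate treatment.
    """

    def both_arms(horizon: float) -> float:
        rm_c = restricted_mean_observation(curve, horizon, strict=strict)
        rm_t = restricted_mean_observation(
            curve, horizon, strict=strict, hazard_power=treatment_hr
        )
        return 0.5 * (rm_c + rm_t)

    if design.kind == "fixed":
        return both_arms(design.duration)
    f, a = design.followup_time, design.accrual_time
    horizons = (f, f + a / 2, f + a)
    return float(sum(w * both_arms(h) for w, h in zip(SIMPSON_WEIGHTS, horizons)))


def analyze(
    dataset: BiomarkerSurvivalDataset,
    design: TrialDesign,
    testing: TestingSpec,
    costs: CostSpec | None = None,
    grid: np.ndarray | None = None,
    estimator: str = "km",
    span: float | None = None,
    B: int = 200,
    seed: int = 0,
    min_n: int = 20,
    strict: bool = True,
) -> EnrichmentTable:
    """Evaluate prognostic enrichment across a grid of biomarker thresholds.

    Per threshold: subgroup survival curve -> event rates (fixed-duration or
    Simpson accrual, per ``design``) -> sample size -> total screened -> cost
    -> cost reduction vs the unenriched (t = 0) row. Standard errors come from
    the delta method for fixed designs and from ``B`` bootstrap resamples for
    accrual designs (``B = 0`` skips bootstrap SEs).
    """
    if dataset.n < min_n:
        raise ConfigurationError(
            f"dataset has n = {dataset.n} < {min_n}; too small for stable estimation"
        )
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or grid[0] != 0.0:
        raise ConfigurationError("threshold grid must include 0 as its first entry")
    if np.any(np.diff(grid) <= 0) or grid[-1] > 0.95:
        raise ConfigurationError("grid must be strictly increasing within [0, 0.95]")
    if estimator not in ("km", "nne"):
        raise ConfigurationError(f"unknown estimator {estimator!r}")
    if estimator == "nne" and design.kind == "accrual":
        raise ConfigurationError(
            "accrual + follow-up designs support the Kaplan-Meier estimator only"
        )

    n0 = events_required(testing)
    hr = testing.treatment_hr
    rng = np.random.default_rng(seed)
    rows: list[EnrichmentRow] = []
    curves: dict[float, SurvivalCurve] = {}
    cost0: float | None = None

    for t in grid:
        try:
            curve = subgroup_curve(dataset, float(t), method=estimator, span=span)
        except ValueError as err:
            raise type(err)(f"threshold {t}: {err}") from err
        if float(t) in CURVE_THRESHOLDS or t == grid[0]:
            curves[float(t)] = curve

        if design.kind == "fixed":
            s, se_s = survival_at(curve, design.duration, strict=strict)
            rates = event_rates_fixed(s, se_s, hr)
            size = sample_size(n0, rates)
            er_se = se_s  # SD(pC) = SD(S)
        else:
            rates = event_rates_accrual(
                curve, design.accrual_time, design.followup_time, hr, strict=strict
            )
            size = sample_size(n0, rates)
            er_se = np.nan
            if B > 0:
                reps = _replicate_statistics(dataset, design, testing, float(t), B, rng)
                er_se = float(np.std(reps["event_rate"], ddof=1))
                ssr = reps["sample_size"]
                ssr = ssr[np.isfinite(ssr)]
                size.sd_n = float(np.std(ssr, ddof=1)) if ssr.size > 1 else np.nan

        screened = total_screened(size.total_n, float(t))
        if costs is not None:
            exp_time = None
            if costs.cost_per_time is not None:
                exp_time = _expected_time_in_trial(curve, design, hr, strict)
            cost = total_cost(size.total_n, float(t), costs, exp_time)
            if cost0 is None:
                cost0 = cost
            reduction = cost_reduction(cost, cost0)
        else:
            cost = np.nan
            reduction = np.nan

        rows.append(
            EnrichmentRow(
                threshold=float(t),
                biomarker_cutoff=biomarker_cutoff(dataset.biomarker, float(t)),
                event_rate_pct=100.0 * rates.p_control,
                event_rate_se=100.0 * er_se,
                treatment_event_rate_pct=100.0 * rates.p_treatment,
                sample_size=size.total_n,
                sample_size_se=size.sd_n,
                total_screened=screened,
                total_cost=cost,
                cost_reduction_pct=reduction,
            )
        )

    metadata = {
        "n": dataset.n,
        "estimator": estimator,
        "span": span,
        "bootstrap_B": B if design.kind == "accrual" else 0,
        "seed": seed,
        "required_events": n0,
        "design": {
            "kind": design.kind,
            "duration": design.duration,
            "accrual_time": design.accrual_time,
            "followup_time": design.followup_time,
        },
        "testing": {
            "alpha": testing.alpha,
            "power": testing.power,
            "treatment_hr": testing.treatment_hr,
        },
        "costs": None
        if costs is None
        else {
            "screening_cost": costs.screening_cost,
            "trial_cost": costs.trial_cost,
            "cost_per_time": costs.cost_per_time,
        },
        "input": dataset.source,
        "orientation_flipped": dataset.orientation_flipped,
    }
    return EnrichmentTable(
        rows=rows, design=design, testing=testing, costs=costs,
        metadata=metadata, curves=curves,
    )


def render_outputs(
    table: EnrichmentTable,
    out_dir: str | Path,
    make_figures: bool = False,
    basename: str = "results",
) -> list[Path]:
    """Write ``results.csv`` and ``run.json`` (and optionally ``figure.png``)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    csv_path = out_dir / f"{basename}.csv"
    write_enrichment_table(table, csv_path)
    written.append(csv_path)

    log_path = out_dir / "run.json"
    with open(log_path, "w") as fh:
        json.dump(table.metadata, fh, indent=2, default=str)
    written.append(log_path)

    if make_figures:
        fig_path = out_dir / f"figure_{basename}.png"
        _render_figure(table, fig_path)
        written.append(fig_path)
    return written


def _render_figure(table: EnrichmentTable, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = table.to_frame()
    thr = frame["threshold"] * 100
    fig, axes = plt.subplots(2, 3, figsize=(13, 7.5))

    ax = axes[0, 0]
    for t, curve in sorted(table.curves.items()):
        ax.step(
            np.concatenate([[0.0], curve.times]),
            np.concatenate([[1.0], curve.surv]),
            where="post",
            label=f"{t:.0%} enrichment",
        )
    if table.design.kind == "fixed":
        ax.axvline(table.design.duration, ls=":", color="grey")
    else:
        ax.axvline(table.design.followup_time, ls=":", color="grey")
        ax.axvline(table.design.max_observation, ls=":", color="grey")
    ax.set_xlabel("time")
    ax.set_ylabel("survival")
    ax.legend(fontsize=8)

    panels = [
        (axes[0, 1], "event_rate_pct_exact", "event_rate_se", "event rate (%)"),
        (axes[0, 2], "sample_size_exact", "sample_size_se", "sample size"),
        (axes[1, 0], "total_screened_exact", None, "total screened"),
        (axes[1, 1], "total_cost", None, "total cost"),
        (axes[1, 2], "cost_reduction_pct", None, "cost reduction (%)"),
    ]
    for ax, col, se_col, label in panels:
        y = frame[col]
        ax.plot(thr, y, marker="o", ms=3)
        if se_col is not None and frame[se_col].notna().any():
            ax.fill_between(thr, y - frame[se_col], y + frame[se_col], alpha=0.25)
        ax.set_xlabel("enrichment level (%)")
        ax.set_ylabel(label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
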