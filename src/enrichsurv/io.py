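"""Reading and validating subject-level biomarker/survival tables, writing results.

The working convention throughout the package is that *higher biomarker values
mean higher risk* of the clinical event. Data in the opposite orientation are
negated on ingestion and the flip is recorded, so every downstream quantile is
computed on the oriented values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterator, NamedTuple

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .analysis import EnrichmentTable

logger = logging.getLogger("enrichsurv")

__all__ = [
    "SubjectRecord",
    "BiomarkerSurvivalDataset",
    "ValidationError",
    "ConfigurationError",
    "read_dataset",
    "write_enrichment_table",
    "round_half_away",
]


class ConfigurationError(ValueError):
    """A run was configured inconsistently (bad column name, bad flag combination)."""


class ValidationError(ValueError):
    """Subject-level data violated the input contract; the message names the row."""


class SubjectRecord(NamedTuple):
    """One subject: oriented biomarker value, observed time, event indicator."""

    biomarker: float
    time: float
    event: int


@dataclass
class BiomarkerSurvivalDataset:
    """A validated sample of subjects with biomarker values and censored times.

    Parameters
    ----------
    biomarker : array of float
        Oriented biomarker values (higher = higher risk). Must be finite.
    time : array of float
        Non-negative observed times (event or censoring), in consistent units.
    event : array of int
        1 if the event was observed at ``time``, 0 if censored.
    orientation_flipped : bool
        True if the raw input biomarker was negated on ingestion.
    """

    biomarker: np.ndarray
    time: np.ndarray
    event: np.ndarray
    orientation_flipped: bool = False
    source: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.biomarker = np.asarray(self.biomarker, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if not (len(self.biomarker) == len(self.time) == len(self.event)):
            raise ValidationError("biomarker, time and event must have equal length")
        bad = np.flatnonzero(~np.isfinite(self.biomarker))
        if bad.size:
            raise ValidationError(f"non-finite biomarker value at row {bad[0]}")
        bad = np.flatnonzero(~np.isfinite(self.time) | (self.time < 0))
        if bad.size:
            raise ValidationError(f"negative or non-finite time at row {bad[0]}")
        ev = np.asarray(self.event, dtype=float)
        bad = np.flatnonzero(~np.isin(ev, (0.0, 1.0)))
        if bad.size:
            raise ValidationError(
                f"event indicator outside {{0, 1}} at row {bad[0]} "
                f"(value {self.event[bad[0]]!r})"
            )
        self.event = ev.astype(np.int64)

    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def records(self) -> Iterator[SubjectRecord]:
        for b, t, e in zip(self.biomarker, self.time, self.event):
            yield SubjectRecord(float(b), float(t), int(e))

    def subset(self, mask: np.ndarray) -> "BiomarkerSurvivalDataset":
        return BiomarkerSurvivalDataset(
            self.biomarker[mask],
            self.time[mask],
            self.event[mask],
            orientation_flipped=self.orientation_flipped,
            source=self.source,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"biomarker": self.biomarker, "time": self.time, "event": self.event}
        )


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", newline="") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def read_dataset(
    path: str | Path,
    biomarker_col: str = "biomarker",
    time_col: str = "time",
    event_col: str = "event",
    higher_is_riskier: bool = True,
    delimiter: str | None = None,
    drop_missing: bool = False,
) -> BiomarkerSurvivalDataset:
    """Read a delimited subject table and validate it.

    The delimiter is auto-detected (comma vs tab) unless given. Missing values
    are an error unless ``drop_missing`` is set, in which case the dropped count
    is logged — silently excluding rows would shift biomarker quantiles.
    If ``higher_is_riskier`` is False the biomarker column is negated so the
    internal convention (higher = riskier) holds.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    sep = delimiter if delimiter is not None else _sniff_delimiter(path)
    frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
    for col in (biomarker_col, time_col, event_col):
        if col not in frame.columns:
            raise ConfigurationError(
                f"column {col!r} not found in {path.name}; available: "
                f"{list(frame.columns)}"
            )
    sub = frame[[biomarker_col, time_col, event_col]].apply(
        pd.to_numeric, errors="coerce"
    )
    missing = sub.isna().any(axis=1)
    if missing.any():
        if drop_missing:
            logger.info("dropping %d rows with missing values", int(missing.sum()))
            sub = sub[~missing]
        else:
            row = int(np.flatnonzero(missing.to_numpy())[0])
            raise ValidationError(
                f"missing or non-numeric value at row {row}; "
                "pass drop_missing to exclude such rows"
            )
    biomarker = sub[biomarker_col].to_numpy(dtype=float)
    if not higher_is_riskier:
        biomarker = -biomarker
    return BiomarkerSurvivalDataset(
        biomarker,
        sub[time_col].to_numpy(dtype=float),
        sub[event_col].to_numpy(),
        orientation_flipped=not higher_is_riskier,
        source=str(path),
    )


def round_half_away(x) -> np.ndarray | float:
    """Round half away from zero (display convention for patient counts / percents)."""
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return float(out) if out.ndim == 0 else out


#: Leading column order of the results table. Display columns are rounded
#: (event rates to whole percent, patient counts to whole patients); the
#: ``*_exact`` columns retain full precision.
TABLE_COLUMNS = [
    "threshold",
    "biomarker_cutoff",
    "event_rate_pct",
    "event_rate_se",
    "sample_size",
    "sample_size_se",
    "total_screened",
    "total_cost",
    "cost_reduction_pct",
    "event_rate_pct_exact",
    "sample_size_exact",
    "total_screened_exact",
    "treatment_event_rate_pct_exact",
]


def write_enrichment_table(table: "EnrichmentTable", path: str | Path) -> None:
    """Write a per-threshold results table as CSV in a fixed column order.

    Full-precision columns survive a write/read round trip exactly
    (``pandas`` writes them with repr-level precision).
    """
    frame = table.to_frame()
    if frame.empty:
        raise ValueError("refusing to write an empty results table")
    frame.to_csv(path, index=False, columns=TABLE_COLUMNS, float_format=None)
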