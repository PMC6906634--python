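"""Per-cell firing statistics: rate, ISI CV, CV2, and cohort summaries.

Rate is spikes per second over the analyzed window.  CV is the coefficient
of variation of the interspike intervals, sd(ISI)/mean(ISI), a global
irregularity measure.  CV2 is the mean over adjacent ISI pairs of
``2*|ISI_{n+1} - ISI_n| / (ISI_{n+1} + ISI_n)``, a local irregularity
measure bounded in [0, 2] that is insensitive to slow rate drift.  CV and
CV2 require at least three spikes (two ISIs); below that they propagate as
NaN and are counted as missing by the group stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import CellRecord, CohortTable, InvalidSpecification, SpikeTrain

__all__ = [
    "CellMetrics",
    "firing_rate",
    "isi_cv",
    "isi_cv2",
    "percent_difference",
    "summarize_cell",
    "metrics_frame",
    "cohort_summary",
]

MIN_SPIKES_FOR_VARIABILITY = 3


@dataclass(frozen=True)
class CellMetrics:
    """Summary statistics of one spike train; cv/cv2 are NaN when undefined."""

    rate_hz: float
    cv: float
    cv2: float
    n_spikes: int
    duration_s: float
    unit_type: str

    def as_row(self) -> dict:
        return {
            "unit_type": self.unit_type,
            "rate_hz": self.rate_hz,
            "cv": self.cv,
            "cv2": self.cv2,
            "n_spikes": self.n_spikes,
            "duration_s": self.duration_s,
        }


def firing_rate(train: SpikeTrain, duration_s: float | None = None) -> float:
    """Mean firing rate, spikes/s, over the analyzed window."""
    dur = train.duration_s if duration_s is None else duration_s
    if dur <= 0:
        raise InvalidSpecification("duration must be positive")
    return train.n_spikes / dur


def _valid_isis(train: SpikeTrain, exclude_spanning: np.ndarray | None) -> np.ndarray | None:
    if train.n_spikes < MIN_SPIKES_FOR_VARIABILITY:
        return None
    isis = train.isis()
    if exclude_spanning is not None and exclude_spanning.size:
        # drop ISIs that bracket an excluded event (e.g. a complex spike)
        left, right = train.times[:-1], train.times[1:]
        idx = np.searchsorted(exclude_spanning, left, side="right")
        spanned = (idx < exclude_spanning.size) & (exclude_spanning[
            np.clip(idx, 0, exclude_spanning.size - 1)] < right)
        isis = isis[~spanned]
        if isis.size < 2:
            return None
    return isis


def isi_cv(train: SpikeTrain, exclude_spanning: np.ndarray | None = None) -> float:
    """sd(ISI)/mean(ISI) with the sample (n-1) standard deviation.

    ``exclude_spanning`` optionally removes ISIs that bracket another unit's
    event (used to drop simple-spike ISIs interrupted by a complex spike).
    """
    isis = _valid_isis(train, exclude_spanning)
    if isis is None:
        return float("nan")
    m = isis.mean()
    return float(isis.std(ddof=1) / m) if m > 0 else float("nan")


def isi_cv2(train: SpikeTrain, exclude_spanning: np.ndarray | None = None) -> float:
    """Mean of 2|ISI_{n+1}-ISI_n|/(ISI_{n+1}+ISI_n) over adjacent pairs."""
    isis = _valid_isis(train, exclude_spanning)
    if isis is None or isis.size < 2:
        return float("nan")
    a, b = isis[1:], isis[:-1]
    return float(np.mean(2.0 * np.abs(a - b) / (a + b)))


def percent_difference(reference: float, other: float, as_int: bool = False) -> float:
    """Percent change of ``other`` relative to ``reference``:
    ``100 * (reference - other) / reference`` (positive when other is lower).

    ``as_int`` rounds to the nearest whole percent, the convention used when
    quoting effect sizes.
    """
    if reference == 0:
        raise InvalidSpecification("reference must be non-zero")
    pct = 100.0 * (reference - other) / reference
    return float(round(pct)) if as_int else float(pct)


def summarize_cell(cell: CellRecord, exclude_cs_spanning: bool = False) -> CellRecord:
    """Attach a :class:`CellMetrics` per unit type present on the record.

    With ``exclude_cs_spanning``, simple-spike ISIs interrupted by a complex
    spike are excluded from the CV/CV2 computation (off by default: the
    formulas are applied literally to the sorted train).
    """
    for unit, train in cell.trains.items():
        excl = None
        if exclude_cs_spanning and unit == "ss" and "cs" in cell.trains:
            excl = cell.trains["cs"].times
        cell.metrics[unit] = CellMetrics(
            rate_hz=firing_rate(train),
            cv=isi_cv(train, excl),
            cv2=isi_cv2(train, excl),
            n_spikes=train.n_spikes,
            duration_s=train.duration_s,
            unit_type=unit,
        )
    return cell


def metrics_frame(cohort: CohortTable, exclude_cs_spanning: bool = False) -> pd.DataFrame:
    """Per-cell metrics table (one row per cell x unit type), metadata joined."""
    rows = []
    for cell in cohort:
        summarize_cell(cell, exclude_cs_spanning)
        for unit in sorted(cell.metrics):
            rows.append({**cell.metadata(), **cell.metrics[unit].as_row()})
    return pd.DataFrame(rows)


def cohort_summary(metrics: pd.DataFrame, group_by: str = "genotype",
                   responses: tuple[str, ...] = ("rate_hz", "cv", "cv2")) -> pd.DataFrame:
    """Mean, s.e.m. and n per metric per (group, unit type).

    s.e.m. uses the sample standard deviation over n cells; it is NaN for
    single-cell groups.  Cells with undefined metrics are excluded per
    metric, with the exclusion count reported in ``n_missing``.
    """
    out = []
    for (grp, unit), sub in metrics.groupby([group_by, "unit_type"]):
        row: dict = {group_by: grp, "unit_type": unit, "n_cells": len(sub)}
        for r in responses:
            vals = sub[r].dropna()
            n = len(vals)
            row[f"{r}_mean"] = vals.mean() if n else float("nan")
            row[f"{r}_sem"] = vals.std(ddof=1) / np.sqrt(n) if n >= 2 else float("nan")
            row[f"{r}_n"] = n
            row[f"{r}_n_missing"] = len(sub) - n
        out.append(row)
    return pd.DataFrame(out)
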