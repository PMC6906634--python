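"""Core containers shared across the pipeline.

The pipeline moves three kinds of objects around: event-time sequences
(:class:`SpikeTrain`), raw extracellular signals (:class:`VoltageTrace`),
and per-cell records grouped into cohorts (:class:`CellRecord`,
:class:`CohortTable`).  All times are seconds, all voltages microvolts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SpikeTrain",
    "VoltageTrace",
    "CellRecord",
    "CohortTable",
    "InvalidSpecification",
]


class InvalidSpecification(ValueError):
    """Raised when a generator or analysis receives an unusable parameterization."""


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered event times (s) for one unit / spike type over a known duration.

    ``duration_s`` is the length of the analyzed recording window, not the
    span between first and last spike.
    """

    times: np.ndarray
    duration_s: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if self.duration_s <= 0:
            raise InvalidSpecification("duration_s must be positive")
        if t.ndim != 1:
            raise InvalidSpecification("times must be one-dimensional")
        if t.size:
            if np.any(np.diff(t) <= 0):
                raise InvalidSpecification("times must be strictly increasing")
            if t[0] < 0 or t[-1] > self.duration_s:
                raise InvalidSpecification("times must lie within [0, duration_s]")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def isis(self) -> np.ndarray:
        """Interspike intervals (s)."""
        return np.diff(self.times)

    def rescaled(self, c: float) -> "SpikeTrain":
        """Multiply all times and the duration by ``c`` (> 0)."""
        if c <= 0:
            raise InvalidSpecification("scale factor must be positive")
        return SpikeTrain(self.times * c, self.duration_s * c)


@dataclass
class VoltageTrace:
    """Uniformly sampled single-channel extracellular signal.

    ``samples`` are microvolts; ``fs_hz`` is the sampling rate.
    ``filter_band_hz`` records the band-pass applied (Hz, low/high edge).
    ``ground_truth`` optionally carries the generating spike times per unit
    type, so detection can be validated against construction.
    """

    samples: np.ndarray
    fs_hz: float
    filter_band_hz: tuple[float, float] | None = None
    ground_truth: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float32)
        if self.fs_hz <= 0:
            raise InvalidSpecification("sampling rate must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz

    def time_axis(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs_hz


@dataclass
class CellRecord:
    """One recorded or simulated cell: metadata plus its spike trains.

    ``trains`` maps unit type (``"ss"``, ``"cs"`` or ``"cn"``) to a
    :class:`SpikeTrain`.  ``metrics`` is filled by the metrics stage.
    """

    cell_id: str
    genotype: str
    state: str
    cell_type: str
    depth_mm: float
    days_post_surgery: float
    duration_s: float
    seed: int
    trains: dict[str, SpikeTrain] = field(default_factory=dict)
    metrics: dict[str, "object"] = field(default_factory=dict)

    def metadata(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "genotype": self.genotype,
            "state": self.state,
            "cell_type": self.cell_type,
            "depth_mm": self.depth_mm,
            "days_post_surgery": self.days_post_surgery,
            "duration_s": self.duration_s,
            "seed": self.seed,
        }


@dataclass
class CohortTable:
    """A collection of :class:`CellRecord` forming the unit of group statistics."""

    cells: list[CellRecord]

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self):
        return iter(self.cells)

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.metadata() for c in self.cells])

    def spikes_frame(self) -> pd.DataFrame:
        """Long-format event table: cell_id, unit_type, time_s."""
        rows = []
        for c in self.cells:
            for unit, train in sorted(c.trains.items()):
                rows.append(
                    pd.DataFrame(
                        {
                            "cell_id": c.cell_id,
                            "unit_type": unit,
                            "time_s": np.round(train.times, 6),
                        }
                    )
                )
        if not rows:
            return pd.DataFrame(columns=["cell_id", "unit_type", "time_s"])
        return pd.concat(rows, ignore_index=True)

    def content_hash(self) -> str:
        """Deterministic digest of metadata + spike times (regeneration check)."""
        import hashlib

        h = hashlib.sha256()
        h.update(self.metadata_frame().to_csv(index=False).encode())
        h.update(self.spikes_frame().to_csv(index=False).encode())
        return h.hexdigest()
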