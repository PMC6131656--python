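"""Shared data containers used across the pipeline.

Units follow patch-clamp and histology conventions throughout the package:
coordinates and radii in micrometres, time in milliseconds (traces) or
seconds (event lists), voltage in millivolts, current in picoamperes,
resistance in megaohms, conductance in nanosiemens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["Trace", "CellMap", "EventList", "SummaryStats"]


@dataclass
class Trace:
    """A uniformly sampled recording sweep.

    Parameters
    ----------
    values : ndarray
        Sample values (mV for voltage, pA for current).
    sampling_interval : float
        Sample spacing in ms.
    units : str
        ``"mV"`` or ``"pA"``.
    protocol : object, optional
        The stimulus protocol that produced the sweep, if any.
    meta : dict
        Free-form provenance (injected current, seed, ...).
    """

    values: np.ndarray
    sampling_interval: float
    units: str = "mV"
    protocol: Any = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("trace must be a 1-D series with >= 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite samples")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")

    @property
    def time(self) -> np.ndarray:
        """Sample times in ms, starting at 0."""
        return np.arange(self.values.size) * self.sampling_interval

    @property
    def duration_ms(self) -> float:
        return (self.values.size - 1) * self.sampling_interval

    def to_csv(self, path) -> None:
        pd.DataFrame({"t_ms": self.time, "value": self.values}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, units: str = "mV") -> "Trace":
        df = pd.read_csv(path)
        t = df.iloc[:, 0].to_numpy(dtype=float)
        dt = float(np.median(np.diff(t)))
        return cls(df.iloc[:, 1].to_numpy(dtype=float), dt, units=units)


class CellMap:
    """Per-section 2-D coordinates of labelled cells.

    Wraps a DataFrame with columns ``section``, ``x_um``, ``y_um`` and an
    optional ``parent_id`` ground-truth column (synthetic data only).
    Sections are 40-um histological slices treated as independent planes.
    """

    REQUIRED = ("section", "x_um", "y_um")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"CellMap missing columns: {missing}")
        if not np.all(np.isfinite(df[["x_um", "y_um"]].to_numpy(dtype=float))):
            raise ValueError("CellMap coordinates must be finite")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sections(self) -> list:
        return sorted(self.df["section"].unique().tolist())

    def section(self, sec) -> pd.DataFrame:
        return self.df[self.df["section"] == sec]

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CellMap":
        return cls(pd.read_csv(Path(path)))


@dataclass
class EventList:
    """Detected (or ground-truth) synaptic events for one recording.

    ``onsets_s`` are event onset times in seconds, strictly increasing;
    amplitudes are absolute magnitudes in pA; half-widths in ms (NaN when
    not measurable).
    """

    onsets_s: np.ndarray
    amplitudes_pa: np.ndarray
    half_widths_ms: np.ndarray
    duration_s: float
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        self.amplitudes_pa = np.asarray(self.amplitudes_pa, dtype=float)
        self.half_widths_ms = np.asarray(self.half_widths_ms, dtype=float)
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if np.any(np.diff(self.onsets_s) <= 0):
            raise ValueError("event onsets must be strictly increasing")

    def __len__(self) -> int:
        return self.onsets_s.size

    @property
    def frequency_hz(self) -> float:
        return len(self) / self.duration_s

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "onset_s": self.onsets_s,
                "amplitude_pA": self.amplitudes_pa,
                "half_width_ms": self.half_widths_ms,
            }
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class SummaryStats:
    """A (mean, SEM, n) triple — the unit of group comparison."""

    mean: float
    sem: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.sem < 0:
            raise ValueError("sem must be non-negative")

    @property
    def sd(self) -> float:
        """Sample standard deviation recovered as sem * sqrt(n)."""
        return self.sem * np.sqrt(self.n)

    @classmethod
    def from_sample(cls, x) -> "SummaryStats":
        x = np.asarray(x, dtype=float)
        return cls(float(np.mean(x)), float(np.std(x, ddof=1) / np.sqrt(x.size)), x.size)
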