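"""Shared in-memory containers for traces, recordings and behavior.

All timestamps are seconds from session start. Activity matrices are
neurons x time-bins; photometry and behavior traces are 1-D series at a
uniform sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ActivityMatrix", "BehaviorTrace", "PhotometryRecording"]


@dataclass
class ActivityMatrix:
    """Neurons x time-bins trace matrix.

    ``units_tag`` records whether values are raw (dF/F-noise style) or
    Z-scored against a baseline period.
    """

    values: np.ndarray
    bin_width: float
    neuron_ids: list[str] = field(default_factory=list)
    units_tag: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D neurons x bins array")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if not self.neuron_ids:
            self.neuron_ids = [f"n{i:03d}" for i in range(self.values.shape[0])]
        if len(self.neuron_ids) != self.values.shape[0]:
            raise ValueError("neuron_ids length must match number of rows")
        if np.isnan(self.values).any():
            raise ValueError("activity contains missing values")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def time_axis(self) -> np.ndarray:
        """Left edge of each time bin, seconds."""
        return np.arange(self.n_bins) * self.bin_width

    @property
    def duration(self) -> float:
        return self.n_bins * self.bin_width

    def to_frame(self) -> pd.DataFrame:
        """Rows = time bins, columns = neuron IDs, index = bin start (s)."""
        return pd.DataFrame(
            self.values.T, index=pd.Index(self.time_axis, name="time"), columns=self.neuron_ids
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, units_tag: str = "raw") -> "ActivityMatrix":
        t = frame.index.to_numpy(dtype=float)
        if len(t) < 2:
            raise ValueError("need at least two time bins")
        bin_width = float(np.median(np.diff(t)))
        return cls(frame.to_numpy().T, bin_width, list(map(str, frame.columns)), units_tag)

    @classmethod
    def from_csv(cls, path, units_tag: str = "raw") -> "ActivityMatrix":
        return cls.from_frame(pd.read_csv(path, index_col=0), units_tag)


@dataclass
class BehaviorTrace:
    """Speed trace (cm/s) at a uniform sampling rate."""

    speed: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.speed = np.asarray(self.speed, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if (self.speed < 0).any():
            raise ValueError("speed must be non-negative")

    @property
    def time_axis(self) -> np.ndarray:
        return np.arange(self.speed.size) / self.sampling_rate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"speed": self.speed}, index=pd.Index(self.time_axis, name="time"))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "BehaviorTrace":
        frame = pd.read_csv(path, index_col=0)
        t = frame.index.to_numpy(dtype=float)
        rate = 1.0 / float(np.median(np.diff(t)))
        return cls(frame["speed"].to_numpy(), rate)


@dataclass
class PhotometryRecording:
    """Paired signal (470 nm) and isosbestic control (405 nm) channels."""

    signal: np.ndarray
    control: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.control = np.asarray(self.control, dtype=float)
        if self.signal.shape != self.control.shape or self.signal.ndim != 1:
            raise ValueError("signal and control must be 1-D series of equal length")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.signal.size

    @property
    def timestamps(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"signal_470": self.signal, "control_405": self.control},
            index=pd.Index(self.timestamps, name="time"),
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "PhotometryRecording":
        frame = pd.read_csv(path, index_col=0)
        t = frame.index.to_numpy(dtype=float)
        rate = 1.0 / float(np.median(np.diff(t)))
        return cls(frame["signal_470"].to_numpy(), frame["control_405"].to_numpy(), rate)
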