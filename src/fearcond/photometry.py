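"""Two-channel fiber-photometry signal processing.

The isosbestic (405 nm) channel captures bleaching and motion common to
both channels but none of the sensor-dependent signal; subtracting its
least-squares affine fit from the 470 nm channel removes that common
mode. Downstream steps normalize sessions to a pre-stimulus baseline,
align signals to events with a 20-s pre-onset Z-score baseline, quantify
signed peri-event AUCs over standard cue/shock windows, and count
supra-threshold transients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .containers import PhotometryRecording

logger = logging.getLogger(__name__)

__all__ = [
    "CorrectionResult",
    "PeriEventTensor",
    "TransientEventSet",
    "NAMED_WINDOWS",
    "correct_control_channel",
    "session_normalize",
    "peri_event_matrix",
    "epoch_auc",
    "detect_transients",
]

#: Cue-locked quantification windows (seconds from cue onset).
NAMED_WINDOWS = {
    "early_tone": (0.0, 10.0),
    "late_tone": (10.0, 28.0),
    "footshock": (28.0, 33.0),
    "post_footshock": (33.0, 50.0),
}


@dataclass
class CorrectionResult:
    corrected: np.ndarray
    mode: str
    slope: float
    intercept: float
    warning: str | None = None


def correct_control_channel(rec: PhotometryRecording, mode: str = "fit-signal") -> CorrectionResult:
    """Remove drift/motion common to both channels using the control channel.

    ``mode='fit-signal'`` (default, standard isosbestic practice) fits the
    control channel to the signal channel by least squares and subtracts
    the fitted control. ``mode='detrend-time'`` instead fits the control
    channel against time and subtracts that fitted linear drift from the
    signal. A constant control channel cannot be scaled; the correction
    falls back to offset-only subtraction with a logged warning.
    """
    if rec.n_samples < 2:
        raise ValueError("need at least two samples")
    sig, ctl, t = rec.signal, rec.control, rec.timestamps
    warning = None
    if mode == "fit-signal":
        if np.ptp(ctl) == 0:
            warning = "constant control channel; offset-only subtraction"
            logger.warning(warning)
            slope, intercept = 0.0, float(ctl[0])
        else:
            slope, intercept = np.polyfit(ctl, sig, 1)
        corrected = sig - (slope * ctl + intercept)
    elif mode == "detrend-time":
        slope, intercept = np.polyfit(t, ctl, 1)
        corrected = sig - (slope * t + intercept)
    else:
        raise ValueError("mode must be 'fit-signal' or 'detrend-time'")
    return CorrectionResult(corrected, mode, float(slope), float(intercept), warning)


def session_normalize(series: np.ndarray, baseline_window: tuple, sampling_rate: float) -> np.ndarray:
    """Z-score a whole-session trace against a pre-stimulus baseline window.

    ``baseline_window`` is (start, end) in seconds. The baseline segment of
    the output has mean 0 and sd 1; the baseline sd sets the scale for the
    whole session.
    """
    series = np.asarray(series, dtype=float)
    i0 = int(round(baseline_window[0] * sampling_rate))
    i1 = int(round(baseline_window[1] * sampling_rate))
    base = series[i0:i1]
    if base.size < 2:
        raise ValueError("baseline window must contain at least two samples")
    sd = base.std()
    if sd == 0:
        raise ValueError("baseline window has zero variance; cannot Z-score")
    return (series - base.mean()) / sd


@dataclass
class PeriEventTensor:
    """Events x time matrix of per-event Z-scored peri-event signal."""

    values: np.ndarray
    time_axis: np.ndarray            # seconds relative to event onset
    baseline_window: tuple
    event_onsets: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (self.event_onsets.size, self.time_axis.size):
            raise ValueError("values must be events x time")


def peri_event_matrix(
    series: np.ndarray,
    event_onsets,
    window: tuple = (-20.0, 50.0),
    baseline: tuple = (-20.0, 0.0),
    sampling_rate: float = 10.0,
) -> PeriEventTensor:
    """Event-aligned matrix, each row Z-scored to its own pre-onset baseline.

    Default baseline is the 20 s preceding onset. Events whose window or
    baseline extends outside the recording are dropped with a log message;
    rows are ordered by event time.
    """
    series = np.asarray(series, dtype=float)
    onsets = np.sort(np.asarray(event_onsets, dtype=float))
    pre, post = window
    lo = min(pre, baseline[0])
    n_pre = int(round(-pre * sampling_rate))
    n_post = int(round(post * sampling_rate))
    rows, kept = [], []
    for onset in onsets:
        c = int(round(onset * sampling_rate))
        b0 = c + int(round(baseline[0] * sampling_rate))
        b1 = c + int(round(baseline[1] * sampling_rate))
        if c - n_pre < 0 or b0 < 0 or c + n_post > series.size:
            logger.warning("event at %.1f s too close to the recording edge; dropped", onset)
            continue
        base = series[b0:b1]
        sd = base.std()
        if sd == 0:
            logger.warning("event at %.1f s has zero-variance baseline; dropped", onset)
            continue
        seg = (series[c - n_pre : c + n_post] - base.mean()) / sd
        rows.append(seg)
        kept.append(onset)
    if not rows:
        raise ValueError("no events with a complete peri-event window")
    time_axis = np.arange(-n_pre, n_post) / sampling_rate
    return PeriEventTensor(np.vstack(rows), time_axis, baseline, np.asarray(kept))


def epoch_auc(tensor: PeriEventTensor, window) -> np.ndarray:
    """Signed trapezoidal area (Z*s) of each event row over a window.

    ``window`` is a named cue-locked window (early_tone, late_tone,
    footshock, post_footshock) or an explicit (start, end) pair in seconds
    relative to event onset.
    """
    if isinstance(window, str):
        if window not in NAMED_WINDOWS:
            raise ValueError(
                f"unknown window {window!r}; valid names: {', '.join(NAMED_WINDOWS)}"
            )
        start, end = NAMED_WINDOWS[window]
    else:
        start, end = window
    t = tensor.time_axis
    mask = (t >= start - 1e-9) & (t <= end + 1e-9)
    if not mask.any():
        raise ValueError("window lies outside the peri-event time axis")
    return np.trapezoid(tensor.values[:, mask], t[mask], axis=1)


@dataclass
class TransientEventSet:
    event_times: np.ndarray
    event_amplitudes: np.ndarray
    detection_threshold: float
    refractory: float

    @property
    def count(self) -> int:
        return int(self.event_times.size)


def detect_transients(
    series: np.ndarray,
    threshold: float = 2.5,
    refractory: float = 1.0,
    sampling_rate: float = 10.0,
    standardize: str = "none",
) -> TransientEventSet:
    """Count supra-threshold transients separated by a refractory interval.

    Events are local maxima at or above ``threshold`` (Z units) whose peaks
    are at least ``refractory`` seconds apart (higher peaks win). With
    ``standardize='robust'`` the series is first converted to a robust
    Z-score (median / 1.4826*MAD), making the default threshold of 2.5
    robust to residual bleach. The event count is monotone non-increasing
    in the threshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    x = np.asarray(series, dtype=float)
    if standardize == "robust":
        mad = np.median(np.abs(x - np.median(x)))
        scale = 1.4826 * mad if mad > 0 else x.std()
        if scale == 0:
            return TransientEventSet(np.array([]), np.array([]), threshold, refractory)
        x = (x - np.median(x)) / scale
    elif standardize != "none":
        raise ValueError("standardize must be 'none' or 'robust'")
    distance = max(1, int(round(refractory * sampling_rate)))
    peaks, props = find_peaks(x, height=threshold, distance=distance)
    return TransientEventSet(
        peaks / sampling_rate, props.get("peak_heights", np.array([])), threshold, refractory
    )
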