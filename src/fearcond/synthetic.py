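"""Synthetic threat-conditioning sessions with known ground truth.

Generates session schedules (tone/shock/ITI timing), neural populations
whose activity follows the same lagged linear model the encoder fits,
two-channel photometry with bleaching and a shared motion artifact, and
speed traces with post-shock freezing bouts. Every generator is fully
deterministic given its seed, so downstream analyses can be tested
against known tuning without any recorded data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal import lfilter

from .containers import ActivityMatrix, BehaviorTrace, PhotometryRecording

logger = logging.getLogger(__name__)

__all__ = [
    "Trial",
    "SessionSchedule",
    "GroundTruthTuning",
    "SimulatedDataset",
    "make_schedule",
    "simulate_population",
    "simulate_behavior",
    "simulate_photometry",
    "inject_state_shift",
    "simulate_dataset",
]

PARADIGMS = ("conditioning", "tone_only", "cue_discrimination")


@dataclass(frozen=True)
class Trial:
    """One cue presentation; shock fields are ``None`` for unpaired cues."""

    tone_on: float
    tone_off: float
    shock_on: float | None
    shock_off: float | None
    cue_id: str = "CS+"

    @property
    def has_shock(self) -> bool:
        return self.shock_on is not None


@dataclass
class SessionSchedule:
    """Timing of baseline, cues, shocks and ITIs within one session."""

    baseline_duration: float
    trials: list[Trial]
    session_end: float
    sampling_rate: float = 10.0
    bin_width: float = 0.5

    def __post_init__(self) -> None:
        if self.baseline_duration < 0 or self.session_end <= 0:
            raise ValueError("durations must be positive")
        if self.sampling_rate <= 0 or self.bin_width <= 0:
            raise ValueError("sampling_rate and bin_width must be positive")
        prev_end = None
        for tr in self.trials:
            if tr.tone_off <= tr.tone_on:
                raise ValueError("tone_off must exceed tone_on")
            if tr.has_shock:
                if not np.isclose(tr.shock_off, tr.tone_off):
                    raise ValueError("shock must co-terminate with tone")
                if tr.shock_on >= tr.shock_off:
                    raise ValueError("shock window must have positive length")
            if tr.tone_on < self.baseline_duration - 1e-9:
                raise ValueError("baseline must precede the first tone")
            if prev_end is not None and tr.tone_on < prev_end - 1e-9:
                raise ValueError("trials overlap in time")
            if tr.tone_off > self.session_end + 1e-9:
                raise ValueError("trial extends past session_end")
            prev_end = tr.tone_off

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_bins(self) -> int:
        return int(round(self.session_end / self.bin_width))

    @property
    def bin_times(self) -> np.ndarray:
        """Left bin edges, seconds."""
        return np.arange(self.n_bins) * self.bin_width

    @property
    def first_shock_onset(self) -> float | None:
        for tr in self.trials:
            if tr.has_shock:
                return tr.shock_on
        return None

    def iti_windows(self, convention: str = "shock_off", post_window_end: float = 50.0):
        """Inter-trial windows, from each trial's end to the next tone.

        ``convention='shock_off'`` starts the ITI at tone/shock offset (the
        default used by the encoder's ITI predictor). ``'post_window_excluded'``
        starts it after the post-shock quantification window (``post_window_end``
        seconds from cue onset) to keep the ITI disjoint from peri-shock
        quantification.
        """
        if convention not in ("shock_off", "post_window_excluded"):
            raise ValueError("convention must be 'shock_off' or 'post_window_excluded'")
        windows = []
        for i, tr in enumerate(self.trials):
            if convention == "shock_off":
                start = tr.tone_off
            else:
                start = min(tr.tone_on + post_window_end, self.session_end)
            end = self.trials[i + 1].tone_on if i + 1 < self.n_trials else self.session_end
            if end - start > 1e-9:
                windows.append((start, end))
        return windows

    def indicator(self, variable: str, trial: int | None = None, **iti_kwargs) -> np.ndarray:
        """Binary per-bin indicator of a task variable (bin midpoint rule).

        ``variable`` is one of ``tone``, ``footshock``, ``iti``. ``trial`` is
        a 1-based trial index; ``None`` pools all trials.
        """
        mid = self.bin_times + self.bin_width / 2.0
        out = np.zeros(self.n_bins)
        trials = self.trials if trial is None else [self._trial(trial)]
        if variable == "tone":
            for tr in trials:
                out[(mid >= tr.tone_on) & (mid < tr.tone_off)] = 1.0
        elif variable == "footshock":
            for tr in trials:
                if tr.has_shock:
                    out[(mid >= tr.shock_on) & (mid < tr.shock_off)] = 1.0
        elif variable == "iti":
            windows = self.iti_windows(**iti_kwargs)
            idx = range(len(windows)) if trial is None else [trial - 1]
            for i in idx:
                if i < len(windows):
                    s, e = windows[i]
                    out[(mid >= s) & (mid < e)] = 1.0
        else:
            raise ValueError(f"unknown task variable {variable!r}")
        return out

    def _trial(self, n: int) -> Trial:
        if not 1 <= n <= self.n_trials:
            raise ValueError(f"trial index {n} out of range 1..{self.n_trials}")
        return self.trials[n - 1]

    def to_json(self, path=None) -> str:
        payload = {
            "baseline_duration": self.baseline_duration,
            "session_end": self.session_end,
            "sampling_rate": self.sampling_rate,
            "bin_width": self.bin_width,
            "trials": [asdict(t) for t in self.trials],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "SessionSchedule":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        trials = [Trial(**t) for t in payload.pop("trials")]
        return cls(trials=trials, **payload)


@dataclass
class GroundTruthTuning:
    """Per-neuron generative weights for the lagged linear model.

    Weight arrays have one entry per kernel lag (lag 0 first) and are shared
    across trials; the AR coefficient multiplies the previous bin's signal.
    ``kernel_tau`` optionally convolves the output with a single-exponential
    calcium kernel (seconds; ``None`` disables it).
    """

    tone: np.ndarray
    footshock: np.ndarray
    iti: np.ndarray
    speed: np.ndarray
    ar_coef: float = 0.0
    noise_sd: float = 1.0
    kernel_tau: float | None = None

    def __post_init__(self) -> None:
        for name in ("tone", "footshock", "iti", "speed"):
            setattr(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        lengths = {getattr(self, n).size for n in ("tone", "footshock", "iti", "speed")}
        if len(lengths) != 1:
            raise ValueError("all weight arrays must share the kernel length")
        if abs(self.ar_coef) >= 1:
            raise ValueError("AR coefficient must satisfy |coef| < 1 (stationarity)")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")

    @property
    def kernel_length(self) -> int:
        return self.tone.size

    @classmethod
    def null(cls, kernel_length: int = 5, ar_coef: float = 0.0, noise_sd: float = 1.0):
        z = np.zeros(kernel_length)
        return cls(z, z.copy(), z.copy(), z.copy(), ar_coef, noise_sd)


@dataclass
class SimulatedDataset:
    """Bundle of one synthetic session and its generating truth."""

    schedule: SessionSchedule
    activity: ActivityMatrix
    truth: list[GroundTruthTuning]
    behavior: BehaviorTrace
    photometry: PhotometryRecording | None
    seed: int

    def __post_init__(self) -> None:
        if len(self.truth) != self.activity.n_neurons:
            raise ValueError("one GroundTruthTuning required per neuron")
        if not np.isclose(self.activity.duration, self.schedule.session_end):
            raise ValueError("activity duration must equal schedule.session_end")


def make_schedule(
    paradigm: str,
    n_trials: int = 6,
    iti=60.0,
    seed: int = 0,
    baseline_duration: float | None = None,
    sampling_rate: float = 10.0,
    bin_width: float = 0.5,
) -> SessionSchedule:
    """Build a session schedule from a named paradigm template.

    ``conditioning``: 30-s tones each co-terminating with a 2-s shock.
    ``tone_only``: identical tone timing, no shocks.
    ``cue_discrimination``: interleaved 10-s CS+ / CS- cues (equal counts,
    CS+ first, random interleaving thereafter), CS+ co-terminating with a
    0.5-s shock, 60-s ITIs.

    ``iti`` may be a scalar or a ``(low, high)`` range sampled per trial.
    """
    if paradigm not in PARADIGMS:
        raise ValueError(f"unknown paradigm {paradigm!r}; available templates: {', '.join(PARADIGMS)}")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)

    def draw_iti() -> float:
        if np.isscalar(iti):
            if iti <= 0:
                raise ValueError("iti must be positive")
            return float(iti)
        lo, hi = iti
        if lo <= 0 or hi < lo:
            raise ValueError("iti range must be positive with high >= low")
        return float(rng.uniform(lo, hi))

    if paradigm in ("conditioning", "tone_only"):
        tone_dur, shock_dur = 30.0, 2.0
        baseline = 300.0 if baseline_duration is None else baseline_duration
        cue_ids = ["CS+"] * n_trials
        shocked = [paradigm == "conditioning"] * n_trials
    else:
        tone_dur, shock_dur = 10.0, 0.5
        baseline = 120.0 if baseline_duration is None else baseline_duration
        if n_trials % 2:
            raise ValueError("cue_discrimination needs an even trial count (equal CS+/CS-)")
        half = n_trials // 2
        rest = ["CS+"] * (half - 1) + ["CS-"] * half
        rng.shuffle(rest)
        cue_ids = ["CS+"] + rest
        shocked = [c == "CS+" for c in cue_ids]

    trials, t = [], baseline
    for k in range(n_trials):
        tone_on, tone_off = t, t + tone_dur
        if shocked[k]:
            trial = Trial(tone_on, tone_off, tone_off - shock_dur, tone_off, cue_ids[k])
        else:
            trial = Trial(tone_on, tone_off, None, None, cue_ids[k])
        trials.append(trial)
        t = tone_off + draw_iti()
    return SessionSchedule(baseline, trials, session_end=t, sampling_rate=sampling_rate, bin_width=bin_width)


def _bin_series(x: np.ndarray, samples_per_bin: int, n_bins: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)[: samples_per_bin * n_bins]
    return x.reshape(n_bins, samples_per_bin).mean(axis=1)


def simulate_population(
    schedule: SessionSchedule,
    truth: list[GroundTruthTuning],
    speed: np.ndarray | BehaviorTrace,
    seed: int = 0,
) -> ActivityMatrix:
    """Simulate binned traces from the lagged linear generative model.

    Each neuron's trace on the schedule's bin grid is

        y_t = ar * y_{t-1} + sum_i w_v[i] * v_{t-i} + sum_i w_s[i] * speed_{t-i} + eps_t

    for task indicators v in {tone, footshock, iti}, optionally convolved
    with a single-exponential calcium kernel. ``speed`` is given at
    ``schedule.sampling_rate`` and binned to the same grid.
    """
    if not truth:
        raise ValueError("truth must contain at least one neuron")
    rng = np.random.default_rng(seed)
    n_bins = schedule.n_bins
    spb = int(round(schedule.bin_width * schedule.sampling_rate))
    speed_arr = speed.speed if isinstance(speed, BehaviorTrace) else np.asarray(speed, float)
    if speed_arr.size < spb * n_bins:
        raise ValueError("speed must cover the session at schedule.sampling_rate")
    speed_binned = _bin_series(speed_arr, spb, n_bins)

    indicators = {v: schedule.indicator(v) for v in ("tone", "footshock", "iti")}
    traces = np.empty((len(truth), n_bins))
    for j, tt in enumerate(truth):
        drive = np.zeros(n_bins)
        for var, ind in indicators.items():
            w = getattr(tt, var)
            for i in range(tt.kernel_length):
                if w[i] != 0.0:
                    drive[i:] += w[i] * ind[: n_bins - i]
        for i in range(tt.kernel_length):
            if tt.speed[i] != 0.0:
                drive[i:] += tt.speed[i] * speed_binned[: n_bins - i]
        drive += rng.normal(0.0, tt.noise_sd, size=n_bins) if tt.noise_sd > 0 else 0.0
        y = lfilter([1.0], [1.0, -tt.ar_coef], drive)
        if tt.kernel_tau is not None:
            k = np.exp(-np.arange(n_bins) * schedule.bin_width / tt.kernel_tau)
            y = lfilter(k, [1.0], y)
        traces[j] = y
    return ActivityMatrix(traces, schedule.bin_width, units_tag="raw")


def simulate_behavior(
    schedule: SessionSchedule,
    freeze_prob_post_shock: float = 0.4,
    seed: int = 0,
    mean_speed: float = 4.0,
    speed_sd: float = 2.0,
    baseline_freeze_prob: float = 0.02,
    mean_bout: float = 2.0,
) -> BehaviorTrace:
    """Simulate a speed trace with elevated post-shock freezing.

    Speed is a clipped AR(1) process around ``mean_speed`` cm/s. Each second
    a freezing bout (sub-threshold speed, exponential duration of mean
    ``mean_bout`` s) starts with probability ``baseline_freeze_prob`` before
    the first shock and ``freeze_prob_post_shock`` afterwards.
    """
    if not 0 <= freeze_prob_post_shock <= 1:
        raise ValueError("freeze_prob_post_shock must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rate = schedule.sampling_rate
    n = int(round(schedule.session_end * rate))
    innov = rng.normal(0.0, speed_sd * np.sqrt(1 - 0.9**2), size=n)
    speed = mean_speed + lfilter([1.0], [1.0, -0.9], innov)
    np.clip(speed, 0.0, None, out=speed)

    first_shock = schedule.first_shock_onset
    t_sec = np.arange(int(schedule.session_end))
    for sec in t_sec:
        p = baseline_freeze_prob
        if first_shock is not None and sec >= first_shock:
            p = freeze_prob_post_shock
        if rng.random() < p:
            dur = rng.exponential(mean_bout)
            i0 = int(sec * rate)
            i1 = min(n, i0 + max(1, int(round(dur * rate))))
            speed[i0:i1] = rng.uniform(0.0, 0.3, size=i1 - i0)
    return BehaviorTrace(speed, rate)


def simulate_photometry(
    schedule: SessionSchedule,
    true_signal: np.ndarray,
    bleach_tau: float = 600.0,
    artifact_sd: float = 0.5,
    seed: int = 0,
    noise_sd: float = 0.02,
    control_scale: float = 0.8,
    bleach_amp: float = 1.0,
) -> PhotometryRecording:
    """Two-channel recording: shared bleach + motion artifact, signal-only truth.

    The signal channel carries ``true_signal`` plus a shared low-frequency
    motion artifact, a monoexponential bleaching drift (decay constant
    ``bleach_tau`` s, amplitude ``bleach_amp``) and white measurement noise.
    The control channel carries a scaled copy of the same artifact and
    bleach but none of the true signal.
    """
    if bleach_tau <= 0:
        raise ValueError("bleach_tau must be positive")
    rng = np.random.default_rng(seed)
    true_signal = np.asarray(true_signal, dtype=float)
    n = true_signal.size
    t = np.arange(n) / schedule.sampling_rate

    if artifact_sd > 0:
        raw = lfilter([1.0], [1.0, -0.98], rng.normal(size=n))
        artifact = artifact_sd * (raw - raw.mean()) / raw.std()
    else:
        artifact = np.zeros(n)
    # drift modeled as a decaying loss of fluorescence (0 at t=0)
    bleach = -bleach_amp * (1.0 - np.exp(-t / bleach_tau)) if np.isfinite(bleach_tau) else np.zeros(n)
    common = artifact + bleach
    signal = true_signal + common + (rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0)
    control = control_scale * common + (rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0)
    return PhotometryRecording(signal, control, schedule.sampling_rate)


def inject_state_shift(
    activity: ActivityMatrix,
    schedule: SessionSchedule,
    shift_gain: float = 1.0,
    shared_factor_sd: float = 0.5,
    seed: int = 0,
) -> ActivityMatrix:
    """Add a post-shock population-state shift to an activity matrix.

    From the first shock onset onward every neuron receives a static offset
    ``shift_gain * l_i`` (random loading ``l_i``), displacing the population
    vector to a new region of state space, plus a shared non-negative latent
    factor ``|f_t|`` with per-neuron loadings that raises the correlation
    between post-shock population vectors. Pre-shock samples are untouched.
    """
    first_shock = schedule.first_shock_onset
    if first_shock is None:
        raise ValueError("schedule has no shock; nothing to shift from")
    rng = np.random.default_rng(seed)
    values = activity.values.copy()
    onset_bin = int(np.floor(first_shock / activity.bin_width))
    n_post = activity.n_bins - onset_bin
    n_neurons = activity.n_neurons

    offset_loadings = rng.normal(size=n_neurons)
    factor_loadings = rng.normal(size=n_neurons)
    if shift_gain != 0.0:
        values[:, onset_bin:] += shift_gain * offset_loadings[:, None]
    if shared_factor_sd > 0.0:
        raw = lfilter([1.0], [1.0, -0.9], rng.normal(size=n_post))
        factor = shared_factor_sd * np.abs(raw) / raw.std()
        values[:, onset_bin:] += factor_loadings[:, None] * factor[None, :]
    return ActivityMatrix(values, activity.bin_width, list(activity.neuron_ids), activity.units_tag)


def simulate_dataset(
    paradigm: str = "conditioning",
    n_trials: int = 6,
    n_neurons: int = 50,
    fraction_tuned: float = 0.2,
    effect_size: float = 1.0,
    noise_sd: float = 0.5,
    ar_coef: float = 0.5,
    kernel_length: int = 5,
    kernel_tau: float | None = None,
    freeze_prob_post_shock: float = 0.4,
    with_photometry: bool = False,
    seed: int = 0,
    **schedule_kwargs,
) -> SimulatedDataset:
    """One-call synthetic session: schedule + tuned population + behavior.

    ``fraction_tuned`` of neurons are given a footshock weight of
    ``effect_size`` at lag 0 (the remainder are pure AR(1) noise neurons).
    """
    ss = np.random.SeedSequence(seed)
    s_sched, s_beh, s_act, s_phot = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4))
    schedule = make_schedule(paradigm, n_trials=n_trials, seed=s_sched, **schedule_kwargs)
    behavior = simulate_behavior(schedule, freeze_prob_post_shock, seed=s_beh)
    n_tuned = int(round(fraction_tuned * n_neurons))
    truth = []
    for j in range(n_neurons):
        tt = GroundTruthTuning.null(kernel_length, ar_coef=ar_coef, noise_sd=noise_sd)
        tt.kernel_tau = kernel_tau
        if j < n_tuned:
            tt.footshock[0] = effect_size
        truth.append(tt)
    activity = simulate_population(schedule, truth, behavior, seed=s_act)
    photometry = None
    if with_photometry:
        n_samples = int(round(schedule.session_end * schedule.sampling_rate))
        ind = schedule.indicator("footshock")
        spb = int(round(schedule.bin_width * schedule.sampling_rate))
        true_sig = np.repeat(ind, spb)[:n_samples]
        photometry = simulate_photometry(schedule, true_sig, seed=s_phot)
    return SimulatedDataset(schedule, activity, truth, behavior, photometry, seed)
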