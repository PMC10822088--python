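"""Behavioral indices and a speed-threshold freezing surrogate.

Freezing is scored as sustained sub-threshold speed (immobility bouts of
at least a minimum duration), standing in for video-based scoring on
synthetic or exported speed traces. The cue-discrimination index,
novel-object difference index and Y-maze spontaneous-alternation
percentage implement their standard closed-form definitions.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import BehaviorTrace

logger = logging.getLogger(__name__)

__all__ = [
    "freezing_mask",
    "freezing_fraction",
    "epoch_freezing_table",
    "discrimination_index",
    "difference_index",
    "alternation_percentage",
]


def freezing_mask(
    trace: BehaviorTrace, speed_threshold: float = 0.5, min_bout: float = 1.0
) -> np.ndarray:
    """Boolean mask of samples inside freezing bouts.

    A bout is a run of speed below ``speed_threshold`` (cm/s) lasting at
    least ``min_bout`` seconds.
    """
    if speed_threshold <= 0:
        raise ValueError("speed_threshold must be positive")
    below = trace.speed < speed_threshold
    min_samples = max(1, int(round(min_bout * trace.sampling_rate)))
    mask = np.zeros_like(below)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], below.view(np.int8), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start >= min_samples:
            mask[start:stop] = True
    return mask


def freezing_fraction(
    trace: BehaviorTrace,
    window: tuple,
    speed_threshold: float = 0.5,
    min_bout: float = 1.0,
) -> float:
    """Fraction of a time window spent inside freezing bouts.

    Bouts are detected on the full trace (so a bout straddling the window
    edge still counts inside it); ``window`` is (start, end) seconds.
    """
    i0 = int(round(window[0] * trace.sampling_rate))
    i1 = int(round(window[1] * trace.sampling_rate))
    if i1 <= i0 or i0 < 0 or i1 > trace.speed.size:
        raise ValueError("window must be non-empty and inside the trace")
    mask = freezing_mask(trace, speed_threshold, min_bout)
    return float(mask[i0:i1].mean())


def epoch_freezing_table(trace: BehaviorTrace, schedule, speed_threshold: float = 0.5,
                         min_bout: float = 1.0):
    """Per-epoch freezing fractions: baseline, each tone, each ITI.

    Returns a list of records (epoch, trial, cue_id, fraction) suitable for
    a DataFrame; cue_id distinguishes CS+ / CS- tones in discrimination
    sessions.
    """
    records = [{
        "epoch": "baseline", "trial": None, "cue_id": None,
        "fraction": freezing_fraction(trace, (0.0, schedule.baseline_duration),
                                      speed_threshold, min_bout),
    }]
    for n, tr in enumerate(schedule.trials, start=1):
        records.append({
            "epoch": "tone", "trial": n, "cue_id": tr.cue_id,
            "fraction": freezing_fraction(trace, (tr.tone_on, tr.tone_off),
                                          speed_threshold, min_bout),
        })
    for n, (s, e) in enumerate(schedule.iti_windows(), start=1):
        records.append({
            "epoch": "iti", "trial": n, "cue_id": None,
            "fraction": freezing_fraction(trace, (s, min(e, trace.time_axis[-1])),
                                          speed_threshold, min_bout),
        })
    return records


def discrimination_index(freeze_csplus: float, freeze_csminus: float) -> float:
    """(F+ - F-) / (F+ + F-); NaN when both freezing fractions are zero."""
    total = freeze_csplus + freeze_csminus
    if total == 0:
        logger.warning("both freezing fractions zero; discrimination index undefined")
        return float("nan")
    return (freeze_csplus - freeze_csminus) / total


def difference_index(time_novel: float, time_familiar: float) -> float:
    """(novel - familiar) / (novel + familiar); NaN when total time is zero."""
    total = time_novel + time_familiar
    if total == 0:
        logger.warning("zero total exploration time; difference index undefined")
        return float("nan")
    return (time_novel - time_familiar) / total


def alternation_percentage(arm_entries, mode: str = "total-entries") -> float:
    """Y-maze spontaneous alternation percentage.

    An alternation is a sliding window of three consecutive entries visiting
    all three arms. The default denominator is the total number of entries
    (x100), the literal scoring convention; ``mode='max-possible'`` divides
    by entries - 2 (the maximum achievable number of alternations) instead.
    Consecutive duplicate entries are rejected; fewer than three entries
    score zero alternations.
    """
    entries = list(arm_entries)
    arms = set(entries)
    if len(arms - set("ABC")) and len(arms) > 3:
        raise ValueError("entries must come from a three-arm alphabet")
    for a, b in zip(entries, entries[1:]):
        if a == b:
            raise ValueError("consecutive duplicate arm entries are not valid")
    if len(entries) < 3:
        return 0.0
    alternations = sum(
        1 for i in range(len(entries) - 2) if len(set(entries[i : i + 3])) == 3
    )
    if mode == "total-entries":
        denom = len(entries)
    elif mode == "max-possible":
        denom = len(entries) - 2
    else:
        raise ValueError("mode must be 'total-entries' or 'max-possible'")
    return 100.0 * alternations / denom
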