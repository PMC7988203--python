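"""Beat extraction and transient-drop features from a BP time series.

Heart rate is read off the pressure signal itself: systolic peaks are
detected, the interval between successive systoles (ISI) gives the
instantaneous rate, and episode-level features (maximal systolic-BP and
HR drops from a pre-stimulus baseline) feed the VVR classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "BeatSeries",
    "DropFeatures",
    "InsufficientBeatsError",
    "detect_systolic_peaks",
    "instantaneous_hr",
    "max_drop",
    "vvr_threshold_label",
    "episode_features",
]


class InsufficientBeatsError(ValueError):
    """Fewer usable systolic peaks than the operation requires."""


@dataclass
class BeatSeries:
    """Per-beat series: systolic peaks, diastolic minima, intervals, HR.

    ``isi[i]`` is the intersystolic interval *following* systole ``i``
    (``peak_times[i+1] - peak_times[i]``) and ``hr_bpm = 60/isi``.
    ``dbp[i]`` is the diastolic minimum preceding systole ``i``.
    """

    peak_times: np.ndarray  # s
    sbp: np.ndarray  # systolic values, mmHg
    dbp: np.ndarray  # preceding diastolic minima, mmHg

    def __post_init__(self) -> None:
        self.peak_times = np.asarray(self.peak_times, dtype=float)
        self.sbp = np.asarray(self.sbp, dtype=float)
        self.dbp = np.asarray(self.dbp, dtype=float)
        if not (len(self.peak_times) == len(self.sbp) == len(self.dbp)):
            raise ValueError("peak_times, sbp, dbp must have equal length")
        if np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("peak_times must be strictly increasing")

    @property
    def isi(self) -> np.ndarray:
        return np.diff(self.peak_times)

    @property
    def hr_bpm(self) -> np.ndarray:
        return 60.0 / self.isi

    def __len__(self) -> int:
        return len(self.peak_times)


@dataclass
class DropFeatures:
    """Episode-level drop features relative to a pre-stimulus baseline."""

    bp_max_drop: float  # mmHg, >= 0
    hr_max_drop: float  # bpm, >= 0
    baseline_sbp: float
    baseline_hr: float
    response_window: tuple


def detect_systolic_peaks(
    t: np.ndarray,
    bp: np.ndarray,
    min_prominence: float | None = None,
    refractory: float = 0.05,
) -> BeatSeries:
    """Detect systolic peaks by prominence, with a refractory period.

    Candidate peaks are strict local maxima with topographic prominence
    at least ``min_prominence`` (default: 25% of the peak-to-peak
    amplitude of the second half of the record, taken as post-transient).
    Candidates closer than ``refractory`` seconds to the last accepted
    peak are pruned greedily, earliest peak first.  ``dbp[i]`` is the
    signal minimum between the preceding accepted peak (or the record
    start) and peak ``i``.
    """
    t = np.asarray(t, dtype=float)
    bp = np.asarray(bp, dtype=float)
    if t.shape != bp.shape:
        raise ValueError("t and bp must have the same shape")
    if not refractory > 0:
        raise ValueError("refractory must be > 0")
    if min_prominence is None:
        tail = bp[bp.shape[0] // 2 :]
        min_prominence = 0.25 * float(tail.max() - tail.min())
        if min_prominence <= 0:
            raise InsufficientBeatsError("insufficient beats: flat signal")
    cand, _ = find_peaks(bp, prominence=min_prominence)
    # greedy earliest-first refractory pruning
    accepted: list[int] = []
    for i in cand:
        if not accepted or t[i] - t[accepted[-1]] >= refractory:
            accepted.append(int(i))
    if len(accepted) < 2:
        raise InsufficientBeatsError(
            f"insufficient beats: found {len(accepted)} peaks, need >= 2"
        )
    idx = np.array(accepted)
    dbp = np.empty(len(idx))
    prev = 0
    for j, i in enumerate(idx):
        dbp[j] = bp[prev:i].min() if i > prev else bp[i]
        prev = i
    return BeatSeries(peak_times=t[idx], sbp=bp[idx], dbp=dbp)


def instantaneous_hr(beats: BeatSeries) -> np.ndarray:
    """Instantaneous heart rate, bpm, one value per intersystolic interval."""
    if len(beats) < 2:
        raise InsufficientBeatsError("need >= 2 peaks for instantaneous HR")
    return beats.hr_bpm


def _window_mask(times: np.ndarray, window: tuple) -> np.ndarray:
    lo, hi = window
    if not lo < hi:
        raise ValueError(f"window must be ordered, got {window}")
    return (times >= lo) & (times <= hi)


def max_drop(
    values: np.ndarray,
    times: np.ndarray,
    baseline_window: tuple,
    response_window: tuple,
) -> float:
    """Peak drop: baseline median minus response minimum, clamped at 0."""
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if baseline_window[1] > response_window[0]:
        raise ValueError("baseline window must precede the response window")
    base = values[_window_mask(times, baseline_window)]
    resp = values[_window_mask(times, response_window)]
    if base.size == 0:
        raise ValueError("empty baseline window")
    if resp.size == 0:
        raise ValueError("empty response window")
    return max(0.0, float(np.median(base) - resp.min()))


def vvr_threshold_label(
    bp_drop: float, hr_drop: float, bp_crit: float = 25.0, hr_crit: float = 25.0
) -> bool:
    """Joint-threshold VVR criterion: both drops at or above their limits.

    The conventional operational definition: a vasovagal response is a
    coordinated drop of at least 25 mmHg in systolic BP *and* 25 bpm in
    HR (inclusive boundaries).
    """
    if bp_drop < 0 or hr_drop < 0:
        raise ValueError("drops must be >= 0")
    return bool(bp_drop >= bp_crit and hr_drop >= hr_crit)


def episode_features(
    beats: BeatSeries,
    baseline_window: tuple,
    response_window: tuple,
) -> DropFeatures:
    """Maximal SBP and HR drops of one episode relative to its baseline.

    HR values are anchored at the time of the systole opening each
    interval (the interval following systole ``i`` belongs to beat ``i``).
    """
    hr_times = beats.peak_times[:-1]
    hr = beats.hr_bpm
    bp_drop = max_drop(beats.sbp, beats.peak_times, baseline_window, response_window)
    hr_drop = max_drop(hr, hr_times, baseline_window, response_window)
    base_sbp = float(np.median(beats.sbp[_window_mask(beats.peak_times, baseline_window)]))
    base_hr = float(np.median(hr[_window_mask(hr_times, baseline_window)]))
    return DropFeatures(
        bp_max_drop=bp_drop,
        hr_max_drop=hr_drop,
        baseline_sbp=base_sbp,
        baseline_hr=base_hr,
        response_window=tuple(response_window),
    )
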