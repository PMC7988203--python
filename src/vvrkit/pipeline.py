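"""End-to-end episode analysis: trace -> beats -> features -> labels.

Glue between the simulator/cohort generator and the analysis modules.
Raw 1-kHz pressure is lightly smoothed (boxcar, default 25 ms — about a
seventh of a beat) and detected peaks are refined sub-sample, so that
telemetry noise does not jitter beat times; everything downstream uses
the per-module operations unchanged.  The analysis settings fixed here
(smoothing width, dBRS increment guard ``eps``, polynomial degree, the
shipped ``tvvr``) were chosen once against the reference synthetic world
and frozen; they are parameters of this pipeline, not of the metrics.
"""

from __future__ import annotations

import numpy as np

from .beats import BeatSeries, detect_systolic_peaks, episode_features, vvr_threshold_label
from .brs import DeltaBRSMax, OnsetResult, delta_brs, delta_brs_max, detect_onset
from .classify import FeaturePoint, classify, evaluate, fit_hyperplane, seed_label
from .cohort import CohortRecord, CohortSpec

__all__ = [
    "beats_from_trace",
    "features_for_episode",
    "cohort_feature_points",
    "run_vvr_pipeline",
    "episode_onset",
]

#: Default pre-detection boxcar width, s.
SMOOTH_S = 0.025
#: Shipped threshold on d(dBRS)/dt for onset detection (calibrated once
#: on the reference synthetic world; negative, crossed downward).
TVVR_DEFAULT = -1e-4


def _boxcar(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    # reflect-pad so the ends are not biased toward zero
    pad = width // 2
    xp = np.concatenate([x[pad:0:-1], x, x[-2 : -pad - 2 : -1]])
    return np.convolve(xp, kernel, mode="valid")[: x.shape[0]]


def _refine_peaks(t, bp, beats: BeatSeries, half_width: int) -> BeatSeries:
    """Sub-sample peak refinement: local parabola around each detected apex.

    A least-squares quadratic over +-half_width samples relocates the
    apex between grid points and de-biases the peak value; measurement
    noise then perturbs peak times by well under a sample instead of
    several milliseconds.
    """
    dt = float(t[1] - t[0])
    idx = np.searchsorted(t, beats.peak_times)
    times = beats.peak_times.copy()
    sbp = beats.sbp.copy()
    for j, i in enumerate(idx):
        lo, hi = i - half_width, i + half_width + 1
        if lo < 0 or hi > bp.shape[0]:
            continue
        x = np.arange(lo, hi) - i
        c = np.polynomial.polynomial.polyfit(x, bp[lo:hi], 2)
        if c[2] >= 0:  # not concave; keep the grid point
            continue
        x0 = -c[1] / (2 * c[2])
        if abs(x0) > half_width:
            continue
        times[j] = t[i] + x0 * dt
        sbp[j] = c[0] + c[1] * x0 + c[2] * x0 * x0
    if np.any(np.diff(times) <= 0):  # refinement must not reorder peaks
        return beats
    return BeatSeries(peak_times=times, sbp=sbp, dbp=beats.dbp)


def beats_from_trace(
    t: np.ndarray,
    bp: np.ndarray,
    smooth_s: float = SMOOTH_S,
    min_prominence: float | None = None,
    refractory: float = 0.05,
    refine_s: float = 0.012,
) -> BeatSeries:
    """Smooth, detect systolic peaks, then refine apex times sub-sample."""
    t = np.asarray(t, dtype=float)
    bp = np.asarray(bp, dtype=float)
    if smooth_s > 0:
        dt = float(t[1] - t[0])
        width = max(1, int(round(smooth_s / dt)))
        bp = _boxcar(bp, width)
    beats = detect_systolic_peaks(
        t, bp, min_prominence=min_prominence, refractory=refractory
    )
    if refine_s > 0:
        half = max(2, int(round(refine_s / float(t[1] - t[0]))))
        beats = _refine_peaks(t, bp, beats, half)
    return beats


def features_for_episode(
    record: CohortRecord,
    spec: CohortSpec,
    window_beats: int = 1,
    eps: float = 2.5,
) -> tuple[FeaturePoint, dict]:
    """Extract the classifier features of one episode.

    Returns the (unlabeled) feature point plus a detail dict with the
    drop features, the joint 25/25 criterion verdict and the beat series.
    """
    tr = record.trace
    beats = beats_from_trace(tr.t, tr.z2)
    drops = episode_features(beats, spec.baseline_window, spec.response_window)
    series = delta_brs(beats, window_beats=window_beats, eps=eps)
    try:
        mx = delta_brs_max(series, spec.response_window)
    except ValueError:
        # no pressure increment above eps in the window: no measurable
        # dBRS excursion
        mx = DeltaBRSMax(0.0, 0.0, float(spec.response_window[0]))
    point = FeaturePoint(
        episode_id=record.episode_id,
        bp_max_drop=drops.bp_max_drop,
        delta_brs_max=mx.magnitude,
    )
    detail = {
        "drops": drops,
        "meets_2525": vvr_threshold_label(drops.bp_max_drop, drops.hr_max_drop),
        "beats": beats,
        "delta_brs": series,
        "delta_brs_max": mx,
    }
    return point, detail


def cohort_feature_points(records, spec: CohortSpec):
    """Feature points plus truth points for a whole cohort."""
    points, truth = [], []
    for rec in records:
        p, _ = features_for_episode(rec, spec)
        points.append(p)
        truth.append(
            FeaturePoint(
                episode_id=rec.episode_id,
                bp_max_drop=p.bp_max_drop,
                delta_brs_max=p.delta_brs_max,
                label=rec.truth,
            )
        )
    return points, truth


def run_vvr_pipeline(
    records,
    spec: CohortSpec,
    vvr_seed_drop: float = 35.0,
    normal_seed_drop: float = 10.0,
    baselines: tuple = (25.0, 18.0),
):
    """Full single-pass pipeline on a cohort.

    Seed-label the extremes of BPmaxdrop, fit the hyperplane on the
    seeds, classify the rest, and evaluate against truth and against the
    single-threshold baselines.  Returns
    ``(predicted_points, truth_points, plane, report)``.
    """
    points, truth = cohort_feature_points(records, spec)
    seeded = seed_label(points, vvr_seed_drop, normal_seed_drop)
    plane = fit_hyperplane(seeded)
    predicted = classify(seeded, plane)
    report = evaluate(predicted, truth, baselines=baselines)
    return predicted, truth, plane, report


def episode_onset(
    record: CohortRecord,
    spec: CohortSpec,
    tvvr: float = TVVR_DEFAULT,
    degree: int = 16,
    window_beats: int = 1,
    eps: float = 2.5,
) -> OnsetResult:
    """Tvvr onset detection for one episode (pipeline analysis settings)."""
    tr = record.trace
    beats = beats_from_trace(tr.t, tr.z2)
    return detect_onset(
        beats,
        baseline_window=spec.baseline_window,
        tvvr=tvvr,
        degree=degree,
        window_beats=window_beats,
        eps=eps,
    )
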