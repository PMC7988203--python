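"""Baroreflex-sensitivity metrics and VVR-onset detection.

Three layers:

* the classic baroreflex sensitivity (BRS): the ordinary least-squares
  slope of the intersystolic interval regressed on the previous systolic
  pressure;
* the instantaneous variant dBRS: a moving-window mean of beat-to-beat
  ratios d(ISI)/d(SBP), which carries simultaneous HR and BP information
  and whose excursion grows sharply at the start of a vasovagal response;
* onset detection: a polynomial fit to the dBRS series is differentiated
  analytically, and the first crossing of a threshold ``tvvr`` by that
  derivative anticipates the systolic-pressure drop, giving a positive
  lead time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from numpy.polynomial import Polynomial
from scipy.stats import linregress

from .beats import BeatSeries, InsufficientBeatsError, _window_mask

__all__ = [
    "BRSResult",
    "DeltaBRSSeries",
    "DeltaBRSMax",
    "PolyFit",
    "OnsetResult",
    "brs_regression",
    "delta_brs",
    "delta_brs_max",
    "fit_polynomial",
    "poly_derivative",
    "detect_tvvr_crossing",
    "onset_lead_time",
]

_DEGENERATE_VAR = 1e-12


@dataclass
class BRSResult:
    """OLS regression of ISI on previous systolic pressure."""

    slope: float  # s per pressure unit
    intercept: float
    r: float
    n_pairs: int
    degenerate: bool  # constant SBP; slope fixed at 0 by convention


def brs_regression(beats: BeatSeries) -> BRSResult:
    """Classic BRS: regress each interval on the systole that opens it.

    Pairs ``(sbp[i], isi[i])``: the interval *following* systole ``i``
    against that systole's pressure.  A constant-pressure series (as a
    noise-free simulation produces) is degenerate: slope and r are 0.
    """
    if len(beats) < 3:
        raise InsufficientBeatsError("BRS regression needs >= 3 beats")
    sbp = beats.sbp[:-1]
    isi = beats.isi
    if float(np.var(sbp)) < _DEGENERATE_VAR:
        return BRSResult(0.0, float(np.mean(isi)), 0.0, len(isi), True)
    reg = linregress(sbp, isi)
    return BRSResult(
        float(reg.slope), float(reg.intercept), float(reg.rvalue), len(isi), False
    )


@dataclass
class DeltaBRSSeries:
    """Windowed instantaneous BRS, anchored at beat times."""

    times: np.ndarray  # s, peak time of the beat closing each window
    values: np.ndarray  # s per pressure unit
    window_beats: int
    eps: float  # |dSBP| below this excludes the ratio
    n_excluded: int


def delta_brs(beats: BeatSeries, window_beats: int = 5, eps: float = 0.5) -> DeltaBRSSeries:
    """Moving-window mean of beat-to-beat ratios d(ISI)/d(SBP).

    Ratio ``i`` is ``(isi[i]-isi[i-1]) / (sbp[i]-sbp[i-1])``; ratios with
    ``|dSBP| < eps`` are excluded (and counted), so near-constant
    pressure cannot blow the ratio up.  Each retained ratio, anchored at
    its beat's peak time, contributes the mean of the most recent
    ``window_beats`` retained ratios.
    """
    if window_beats < 1:
        raise ValueError("window_beats must be >= 1")
    if not eps > 0:
        raise ValueError("eps must be > 0")
    isi = beats.isi
    sbp = beats.sbp
    times = []
    values = []
    retained: list[float] = []
    n_excluded = 0
    for i in range(1, len(isi)):
        dsbp = sbp[i] - sbp[i - 1]
        if abs(dsbp) < eps:
            n_excluded += 1
            continue
        retained.append((isi[i] - isi[i - 1]) / dsbp)
        window = retained[-window_beats:]
        values.append(sum(window) / len(window))
        times.append(beats.peak_times[i])
    if not retained:
        raise InsufficientBeatsError(
            "no retained dBRS ratios (all pressure increments below eps)"
        )
    return DeltaBRSSeries(
        times=np.array(times),
        values=np.array(values),
        window_beats=window_beats,
        eps=eps,
        n_excluded=n_excluded,
    )


class DeltaBRSMax(NamedTuple):
    """Largest-magnitude dBRS value in a window, with its sign kept."""

    magnitude: float
    signed: float
    time: float


def delta_brs_max(series: DeltaBRSSeries, response_window: tuple) -> DeltaBRSMax:
    """Maximum |dBRS| within the window (signed value reported too)."""
    m = _window_mask(series.times, response_window)
    if not np.any(m):
        raise ValueError("response window does not overlap the dBRS series")
    vals = series.values[m]
    times = series.times[m]
    i = int(np.argmax(np.abs(vals)))
    return DeltaBRSMax(
        magnitude=float(abs(vals[i])), signed=float(vals[i]), time=float(times[i])
    )


@dataclass
class PolyFit:
    """Least-squares polynomial on a rescaled abscissa.

    Wraps :class:`numpy.polynomial.Polynomial`, which maps the data
    domain onto [-1, 1] before fitting for conditioning and applies the
    chain rule on differentiation.
    """

    poly: Polynomial
    rms_residual: float

    @property
    def domain(self) -> tuple:
        return (float(self.poly.domain[0]), float(self.poly.domain[1]))

    def __call__(self, t) -> np.ndarray:
        return self.poly(t)


def fit_polynomial(series: DeltaBRSSeries, degree: int = 8) -> PolyFit:
    """Fit a polynomial to the dBRS series (intermediate step for the derivative)."""
    if degree < 1:
        raise ValueError("degree must be >= 1")
    n = len(series.times)
    if n <= degree:
        raise ValueError(f"need more than {degree} points, got {n}")
    poly = Polynomial.fit(series.times, series.values, deg=degree)
    resid = series.values - poly(series.times)
    return PolyFit(poly=poly, rms_residual=float(np.sqrt(np.mean(resid**2))))


def poly_derivative(fit: PolyFit) -> PolyFit:
    """Analytic derivative on the same domain (rescaling chain rule included)."""
    return PolyFit(poly=fit.poly.deriv(), rms_residual=float("nan"))


def detect_tvvr_crossing(
    deriv: PolyFit,
    tvvr: float,
    direction: str = "below",
    n_grid: int = 4000,
) -> float | None:
    """Earliest time the dBRS derivative crosses the threshold ``tvvr``.

    ``direction``: ``below`` (value <= tvvr, the default — during a VVR
    the interval lengthens while pressure falls, so the fitted dBRS
    trends negative), ``above`` (value >= tvvr) or ``magnitude``
    (|value| >= |tvvr|).  Evaluation is on a dense uniform grid over the
    fit domain; returns ``None`` when the condition never holds.
    """
    if not np.isfinite(tvvr):
        raise ValueError("tvvr must be finite")
    lo, hi = deriv.domain
    if not lo < hi:
        raise ValueError("empty fit domain")
    t = np.linspace(lo, hi, n_grid)
    y = deriv(t)
    if direction == "below":
        hit = y <= tvvr
    elif direction == "above":
        hit = y >= tvvr
    elif direction == "magnitude":
        hit = np.abs(y) >= abs(tvvr)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    idx = np.flatnonzero(hit)
    return float(t[idx[0]]) if idx.size else None


@dataclass
class OnsetResult:
    """Tvvr crossing vs. systolic-drop onset for one episode."""

    tvvr: float
    crossing_time: float | None
    bp_drop_onset_time: float | None
    lead_time: float | None  # positive: the crossing anticipates the drop
    poly_degree: int


def bp_drop_onset(
    beats: BeatSeries,
    baseline_window: tuple,
    drop_fraction: float = 0.5,
) -> float | None:
    """First beat whose SBP falls ``drop_fraction`` of the way to the minimum.

    Onset is the first peak time with
    ``sbp < median(baseline) - drop_fraction*(median(baseline) - min(sbp))``;
    ``None`` when the series never qualifies (no real drop).
    """
    if not 0 < drop_fraction <= 1:
        raise ValueError("drop_fraction must lie in (0, 1]")
    base = beats.sbp[_window_mask(beats.peak_times, baseline_window)]
    if base.size == 0:
        raise ValueError("empty baseline window")
    med = float(np.median(base))
    floor = float(beats.sbp.min())
    if floor >= med:
        return None
    thresh = med - drop_fraction * (med - floor)
    after = beats.peak_times > baseline_window[1]
    qual = after & (beats.sbp < thresh)
    idx = np.flatnonzero(qual)
    return float(beats.peak_times[idx[0]]) if idx.size else None


def onset_lead_time(
    crossing_time: float | None,
    beats: BeatSeries,
    baseline_window: tuple,
    drop_fraction: float = 0.5,
    tvvr: float = float("nan"),
    poly_degree: int = 8,
) -> OnsetResult:
    """Lead time between the Tvvr crossing and the systolic-drop onset."""
    onset = bp_drop_onset(beats, baseline_window, drop_fraction)
    lead = None
    if crossing_time is not None and onset is not None:
        lead = onset - crossing_time
    return OnsetResult(
        tvvr=tvvr,
        crossing_time=crossing_time,
        bp_drop_onset_time=onset,
        lead_time=lead,
        poly_degree=poly_degree,
    )


def detect_onset(
    beats: BeatSeries,
    baseline_window: tuple,
    analysis_window: tuple | None = None,
    tvvr: float = -0.002,
    direction: str = "below",
    degree: int = 8,
    window_beats: int = 5,
    eps: float = 0.5,
    drop_fraction: float = 0.5,
) -> OnsetResult:
    """Full onset pipeline: dBRS -> polynomial -> derivative -> crossing.

    Convenience wrapper tying the individual steps together for one
    episode.  ``analysis_window`` restricts the dBRS series used in the
    polynomial fit (default: everything from the baseline start on).
    """
    series = delta_brs(beats, window_beats=window_beats, eps=eps)
    if analysis_window is not None:
        m = _window_mask(series.times, analysis_window)
        if np.count_nonzero(m) <= degree:
            raise InsufficientBeatsError("too few dBRS points in analysis window")
        series = DeltaBRSSeries(
            times=series.times[m],
            values=series.values[m],
            window_beats=series.window_beats,
            eps=series.eps,
            n_excluded=series.n_excluded,
        )
    fit = fit_polynomial(series, degree=degree)
    deriv = poly_derivative(fit)
    crossing = detect_tvvr_crossing(deriv, tvvr, direction=direction)
    return onset_lead_time(
        crossing, beats, baseline_window, drop_fraction, tvvr=tvvr, poly_degree=degree
    )
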