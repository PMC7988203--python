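"""Discrete-time relaxation-oscillator model of arterial blood pressure.

The model is a second-order discrete oscillator with two states, ``x1``
and ``x2``, coupled through unit-delay leaky integrators.  A piecewise
linear threshold/saturation element ``f1`` in the negative-feedback path
makes the system oscillate between a slow (diastolic) and a fast
(systolic) phase.  A central drive signal, the desired blood pressure
``BP_d``, maintains the oscillation: its level sets both the oscillation
amplitude and the beat period, so a drop in ``BP_d`` lowers systolic
pressure and slows the beat simultaneously — the mechanism of a
vasovagal response (VVR) in this model.  Vestibular input ``V0`` enters
the same feedback loop through the gain ``g_v``.

The measured pressure output ``z2`` is produced by a shaping path: the
derivative of ``x2`` passes through an odd saturating nonlinearity
``f2``, a first-order high-pass filter (cut-in 0.1 Hz, which prevents
drift at the downstream integrator), and an integrator whose output
``x2p`` is combined with the drive as ``z2 = h6*x2p + g2*BP_d - bias``.

Update rules (step ``n``, step size ``dt``)::

    x1[n+1] = leak1*x1[n] + dt*(BP_d[n] + g_v*V0[n] - f1(x2[n]))
    x2[n+1] = leak2*x2[n] + dt*x1[n]
    f1(u)   = clip(k*(u - T), 0, S)
    d[n]    = (x2[n] - x2[n-1])/dt
    x2p[n]  = x2p[n-1] + dt*HP(f2(d[n]));  f2(d) = clip(f2_slope*d, -f2_sat, f2_sat)
    z2[n]   = h6*x2p[n] + g2*BP_d[n] - bias

With ``sigma_T > 0`` the threshold ``T`` is perturbed by a Gaussian draw
once per cycle (at the diastole-to-systole transition), which produces
beat-to-beat variability in both systolic level and beat interval and,
through their covariation, a positive baroreflex-sensitivity slope.

The shipped :data:`REFERENCE` parameter set is a calibrated reference
configuration, not a set of published constants: the feedback threshold
``T = -100`` and the drive levels ``BP_d = 50`` (rest) and ``40``
(during a VVR) are the published operating points; every other value was
calibrated once against the published model behaviour (oscillation at a
rat-like rate near 6 Hz, amplitude and rate both increasing with
``BP_d``, and the four published baroreflex-sensitivity slopes) and then
frozen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Sequence

import numpy as np

from ._engine import run_oscillator

__all__ = [
    "OscillatorParams",
    "BPdSchedule",
    "StimulusProfile",
    "SimTrace",
    "NonOscillatingError",
    "REFERENCE",
    "REFERENCE_BPD",
    "f1_threshold_saturation",
    "f2_shape",
    "highpass_first_order",
    "make_stimulus",
    "simulate",
]

#: Reference resting drive level (the published resting operating point).
REFERENCE_BPD = 50.0


class NonOscillatingError(ValueError):
    """Raised when a parameter set fails the oscillation self-test."""


@dataclass(frozen=True)
class OscillatorParams:
    """All constants of the oscillator and its output shaping path.

    Defaults are the calibrated reference set (see module docstring).
    """

    dt: float = 1e-3  # step size, s (1 kHz, matching telemetric sampling)
    T: float = -100.0  # feedback threshold (published value)
    S: float = 400.0  # feedback saturation
    k: float = 4e4  # f1 linear-region slope
    leak1: float = 0.996  # per-step retention of the x1 integrator
    leak2: float = 1.0  # per-step retention of the x2 integrator
    g_v: float = -2.0  # vestibular input gain (negative: vestibular
    #   activation inhibits the drive, so tilt/sGVS push toward a VVR)
    h6: float = -300.0  # x2p output gain (sign sets fast-rise systole)
    g2: float = 3.5  # BP_d output gain
    bias: float = 70.92  # output offset (systolic level 120 at BP_d=50)
    fc: float = 0.1  # high-pass cut-in frequency, Hz (published value)
    f2_sat: float = 6.0  # saturation level of f2
    f2_slope: float = 1.0  # linear-region slope of f2
    sigma_T: float = 0.0003  # SD of per-cycle threshold perturbation
    seed: int = 0  # RNG seed for the threshold noise

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if not self.S > 0:
            raise ValueError("S must be > 0")
        if not self.fc > 0:
            raise ValueError("fc must be > 0")
        for name in ("leak1", "leak2"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.sigma_T < 0:
            raise ValueError("sigma_T must be >= 0")
        if not self.f2_sat > 0:
            raise ValueError("f2_sat must be > 0")

    def with_(self, **kwargs) -> "OscillatorParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


#: The calibrated reference parameter set.
REFERENCE = OscillatorParams()


@dataclass(frozen=True)
class BPdSchedule:
    """Piecewise-constant schedule of the desired-blood-pressure drive.

    ``events`` is an ordered sequence of ``(time_s, level)`` pairs; the
    drive holds each level until the next event time.
    """

    events: tuple = ((0.0, REFERENCE_BPD),)

    def __post_init__(self) -> None:
        ev = tuple((float(t), float(v)) for t, v in self.events)
        object.__setattr__(self, "events", ev)
        if not ev:
            raise ValueError("schedule needs at least one event")
        if ev[0][0] != 0.0:
            raise ValueError("first event must be at time 0")
        times = [t for t, _ in ev]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        if any(v < 0 for _, v in ev):
            raise ValueError("BP_d levels must be >= 0")

    @classmethod
    def constant(cls, level: float = REFERENCE_BPD) -> "BPdSchedule":
        return cls(((0.0, level),))

    @classmethod
    def step(cls, before: float, after: float, at: float) -> "BPdSchedule":
        """Schedule holding ``before`` then dropping/stepping to ``after`` at ``at``."""
        return cls(((0.0, before), (at, after)))

    def realize(self, t: np.ndarray) -> np.ndarray:
        """Sample the schedule on a time grid."""
        times = np.array([e[0] for e in self.events])
        levels = np.array([e[1] for e in self.events])
        idx = np.searchsorted(times, t, side="right") - 1
        return levels[idx]


@dataclass(frozen=True)
class StimulusProfile:
    """Vestibular (otolith) input ``V0``.

    ``sgvs`` is a sinusoid at ``freq`` Hz between ``onset`` and
    ``offset``; ``tilt`` is a step of magnitude ``amplitude*sin(angle)``
    over the same window; ``custom`` carries an explicit sample array.
    """

    kind: str = "none"  # none | sgvs | tilt | custom
    freq: float = 0.0  # Hz (sgvs)
    amplitude: float = 0.0
    onset: float = 0.0
    offset: float = 0.0
    angle: float = 0.0  # degrees (tilt)
    samples: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "sgvs", "tilt", "custom"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.kind == "sgvs" and not self.freq > 0:
            raise ValueError("sgvs stimulus requires freq > 0")
        if self.kind in ("sgvs", "tilt") and not self.onset < self.offset:
            raise ValueError("stimulus requires onset < offset")
        if self.kind == "custom" and self.samples is None:
            raise ValueError("custom stimulus requires samples")

    def realize(self, t: np.ndarray) -> np.ndarray:
        if self.kind == "none":
            return np.zeros_like(t)
        if self.kind == "custom":
            s = np.asarray(self.samples, dtype=float)
            if s.shape != t.shape:
                raise ValueError(
                    f"custom stimulus has {s.shape[0]} samples, grid has {t.shape[0]}"
                )
            return s
        active = (t >= self.onset) & (t < self.offset)
        v0 = np.zeros_like(t)
        if self.kind == "sgvs":
            v0[active] = self.amplitude * np.sin(
                2 * math.pi * self.freq * (t[active] - self.onset)
            )
        else:  # tilt
            v0[active] = self.amplitude * math.sin(math.radians(self.angle))
        return v0


def make_stimulus(
    kind: str = "none",
    freq: float = 0.0,
    amplitude: float = 0.0,
    onset: float = 0.0,
    offset: float = 0.0,
    angle: float = 0.0,
    dt: float | None = None,
    samples: Sequence[float] | None = None,
) -> StimulusProfile:
    """Build a :class:`StimulusProfile`, validating against the grid."""
    if kind == "sgvs" and dt is not None and not 0 < freq < 1 / (2 * dt):
        raise ValueError(
            f"sgvs frequency {freq} Hz outside (0, {1 / (2 * dt):g}) for dt={dt}"
        )
    arr = None if samples is None else np.asarray(samples, dtype=float)
    return StimulusProfile(
        kind=kind,
        freq=freq,
        amplitude=amplitude,
        onset=onset,
        offset=offset,
        angle=angle,
        samples=arr,
    )


@dataclass
class SimTrace:
    """Simulated trace: uniform time grid plus all model signals."""

    t: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    x2p: np.ndarray
    z2: np.ndarray  # model blood-pressure output, mmHg-equivalent
    bpd: np.ndarray
    v0: np.ndarray

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def __post_init__(self) -> None:
        n = self.t.shape[0]
        for name in ("x1", "x2", "x2p", "z2", "bpd", "v0"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} length differs from time grid")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.t,
                "x1": self.x1,
                "x2": self.x2,
                "x2p": self.x2p,
                "z2": self.z2,
                "bpd": self.bpd,
                "v0": self.v0,
            }
        )


def f1_threshold_saturation(u, T: float, S: float, k: float = 1.0):
    """Piecewise-linear threshold/saturation feedback element.

    Returns ``clip(k*(u - T), 0, S)``: zero below the threshold ``T``,
    linear with slope ``k`` above it, saturating at ``S``.
    """
    if not S > 0:
        raise ValueError("S must be > 0")
    if not k > 0:
        raise ValueError("k must be > 0")
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite input to f1")
    out = np.clip(k * (u - T), 0.0, S)
    return float(out) if out.ndim == 0 else out


def f2_shape(d, f2_sat: float, f2_slope: float = 1.0):
    """Odd saturating piecewise-linear shaping of the ``x2`` derivative."""
    if not f2_sat > 0:
        raise ValueError("f2_sat must be > 0")
    d = np.asarray(d, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite input to f2")
    out = np.clip(f2_slope * d, -f2_sat, f2_sat)
    return float(out) if out.ndim == 0 else out


def hp_coefficient(fc: float, dt: float) -> float:
    """Discrete coefficient ``a = tau/(tau + dt)`` with ``tau = 1/(2*pi*fc)``."""
    if not fc > 0 or not dt > 0:
        raise ValueError("fc and dt must be > 0")
    tau = 1.0 / (2 * math.pi * fc)
    return tau / (tau + dt)


def highpass_first_order(x, fc: float, dt: float) -> np.ndarray:
    """First-order high-pass filter ``y[n] = a*(y[n-1] + x[n] - x[n-1])``.

    Initial conditions ``y[-1] = x[-1] = 0``; rejects DC exactly in the
    long run.
    """
    a = hp_coefficient(fc, dt)
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return x.copy()
    y = np.empty_like(x)
    y_prev = 0.0
    x_prev = 0.0
    for i in range(x.shape[0]):
        y_prev = a * (y_prev + x[i] - x_prev)
        x_prev = x[i]
        y[i] = y_prev
    return y


def _count_cycles(x1: np.ndarray) -> int:
    """Number of completed oscillation cycles (x1 sign changes + -> -)."""
    return int(np.count_nonzero((x1[:-1] > 0) & (x1[1:] <= 0)))


@lru_cache(maxsize=32)
def _oscillation_probe(params: OscillatorParams) -> bool:
    """Probe the parameter set at the reference drive; True if it cycles."""
    probe = params.with_(sigma_T=0.0)
    n = int(round(6.0 / params.dt))
    bpd = np.full(n, REFERENCE_BPD)
    v0 = np.zeros(n)
    noise = np.zeros(1)
    x1, x2, _, _ = run_oscillator(
        probe.dt, probe.T, probe.S, probe.k, probe.leak1, probe.leak2,
        probe.g_v, hp_coefficient(probe.fc, probe.dt), probe.f2_sat,
        probe.f2_slope, probe.h6, probe.g2, probe.bias, 0.0,
        bpd, v0, noise, 0.0, probe.T,
    )
    half = x1[n // 2 :]
    return _count_cycles(half) >= 3


def simulate(
    params: OscillatorParams = REFERENCE,
    bpd: BPdSchedule | float = REFERENCE_BPD,
    stim: StimulusProfile | None = None,
    duration: float = 60.0,
    check_oscillation: bool = True,
) -> SimTrace:
    """Run the oscillator and return the full simulated trace.

    ``bpd`` may be a schedule or a constant level.  The parameter set is
    first checked by a short self-test at the reference drive level
    (``BP_d = 50``); a configuration that cannot sustain at least three
    oscillation cycles there raises :class:`NonOscillatingError` rather
    than silently returning a flat trace.  (The check concerns the
    parameter set, not the schedule: driving a healthy configuration
    with ``BP_d = 0`` legitimately returns a decaying trace.)
    """
    if isinstance(bpd, (int, float)):
        bpd = BPdSchedule.constant(float(bpd))
    if stim is None:
        stim = StimulusProfile()
    if not duration > 0:
        raise ValueError("duration must be > 0")
    if check_oscillation and not _oscillation_probe(params):
        raise NonOscillatingError(
            "non-oscillating configuration: parameter set fails the "
            "3-cycle self-test at the reference drive level"
        )
    n = int(round(duration / params.dt))
    t = np.arange(n) * params.dt
    bpd_arr = bpd.realize(t)
    v0_arr = stim.realize(t)
    rng = np.random.default_rng(params.seed)
    # one draw per step is a safe upper bound on per-cycle redraws
    noise = rng.standard_normal(n + 1) if params.sigma_T > 0 else np.zeros(1)
    x1, x2, x2p, z2 = run_oscillator(
        params.dt, params.T, params.S, params.k, params.leak1, params.leak2,
        params.g_v, hp_coefficient(params.fc, params.dt), params.f2_sat,
        params.f2_slope, params.h6, params.g2, params.bias, params.sigma_T,
        bpd_arr, v0_arr, noise, 0.0, params.T,
    )
    return SimTrace(t=t, x1=x1, x2=x2, x2p=x2p, z2=z2, bpd=bpd_arr, v0=v0_arr)
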