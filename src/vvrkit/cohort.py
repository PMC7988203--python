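"""Synthetic labeled cohorts of normal and VVR blood-pressure episodes.

Episodes are generated mechanistically: every trace comes out of the
relaxation oscillator with per-cycle threshold noise, a vestibular
stimulus, and — for VVR episodes only — a drop in the desired-pressure
drive BP_d injected at a random time, which is the model's mechanism for
a vasovagal response (simultaneous fall of systolic pressure and heart
rate).  Gaussian measurement noise is added to the pressure output only.
Because the drop is produced by the same dynamics the analysis pipeline
assumes, feature statistics (BPmaxdrop, dBRS excursions, lead times)
inherit the model's covariance structure rather than being painted on.

Defaults state the emulated world: 20+20 episodes of 150 s at 1 kHz,
drive drops of 15-30% of the resting level (the published VVR simulation
drops BP_d by 20%), low-frequency sGVS during the response period, and
1 mmHg telemetry noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np

from .oscillator import (
    REFERENCE,
    REFERENCE_BPD,
    BPdSchedule,
    OscillatorParams,
    SimTrace,
    StimulusProfile,
    simulate,
)

__all__ = ["CohortSpec", "CohortRecord", "generate_cohort", "add_measurement_noise"]


def _default_stimulus() -> StimulusProfile:
    # low-frequency sGVS during the response period
    return StimulusProfile(
        kind="sgvs", freq=0.025, amplitude=1.5, onset=70.0, offset=150.0
    )


@dataclass(frozen=True)
class CohortSpec:
    """Stated world of one synthetic cohort."""

    n_vvr: int = 20
    n_normal: int = 20
    bpd_drop_range: tuple = (7.5, 15.0)  # 15-30% of the resting drive
    drop_time_range: tuple = (80.0, 110.0)  # s, after stimulus onset
    drop_ramp_s: float = 1.0  # drive declines linearly over this long
    measurement_noise_sd: float = 1.0  # mmHg
    sigma_T: float = REFERENCE.sigma_T
    duration: float = 150.0  # s
    baseline_window: tuple = (10.0, 70.0)  # s, pre-stimulus
    stimulus: StimulusProfile = field(default_factory=_default_stimulus)
    params: OscillatorParams = REFERENCE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vvr < 0 or self.n_normal < 0:
            raise ValueError("episode counts must be >= 0")
        if not self.bpd_drop_range[0] <= self.bpd_drop_range[1]:
            raise ValueError("bpd_drop_range must be ordered")
        if not self.drop_time_range[0] <= self.drop_time_range[1]:
            raise ValueError("drop_time_range must be ordered")
        if self.measurement_noise_sd < 0:
            raise ValueError("measurement_noise_sd must be >= 0")

    @property
    def response_window(self) -> tuple:
        return (self.stimulus.onset, self.duration)


@dataclass
class CohortRecord:
    """One generated episode with its ground truth and provenance."""

    episode_id: str
    trace: SimTrace
    truth: str  # "vvr" | "normal"
    drop_magnitude: float  # 0 for normal episodes
    drop_time: float | None
    seed: int


def _ramp_schedule(
    before: float, after: float, at: float, ramp_s: float, n_sub: int = 8
) -> BPdSchedule:
    """Linear drive decline realized as fine piecewise-constant steps.

    A vasovagal drive drop develops over a short but nonzero time; a
    one-second ramp keeps consecutive beats coherently coordinated
    (falling pressure with lengthening interval) instead of exciting a
    single anomalous transition beat.
    """
    if ramp_s <= 0:
        return BPdSchedule.step(before, after, at)
    events = [(0.0, before)]
    for j in range(1, n_sub + 1):
        frac = j / n_sub
        events.append((at + frac * ramp_s, before + frac * (after - before)))
    return BPdSchedule(tuple(events))


def add_measurement_noise(trace: SimTrace, sd: float, seed: int) -> SimTrace:
    """Additive i.i.d. Gaussian noise on the pressure output z2 only."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return trace
    rng = np.random.default_rng(seed)
    return _dc_replace(trace, z2=trace.z2 + rng.normal(0.0, sd, trace.z2.shape[0]))


def generate_cohort(spec: CohortSpec) -> list[CohortRecord]:
    """Generate the cohort, fully reproducible from ``spec.seed``."""
    ss = np.random.SeedSequence(spec.seed)
    n = spec.n_vvr + spec.n_normal
    children = ss.spawn(n)
    records = []
    for i in range(n):
        is_vvr = i < spec.n_vvr
        child = children[i]
        # independent streams: episode randomization, oscillator threshold
        # noise, and measurement noise
        s_draw, s_osc, s_meas = (
            int(s.generate_state(1)[0] % (2**31)) for s in child.spawn(3)
        )
        rng = np.random.default_rng(s_draw)
        if is_vvr:
            mag = float(rng.uniform(*spec.bpd_drop_range))
            t_drop = float(rng.uniform(*spec.drop_time_range))
            schedule = _ramp_schedule(
                REFERENCE_BPD, REFERENCE_BPD - mag, t_drop, spec.drop_ramp_s
            )
        else:
            mag, t_drop = 0.0, None
            schedule = BPdSchedule.constant(REFERENCE_BPD)
        params = spec.params.with_(sigma_T=spec.sigma_T, seed=s_osc)
        trace = simulate(
            params, bpd=schedule, stim=spec.stimulus, duration=spec.duration
        )
        trace = add_measurement_noise(trace, spec.measurement_noise_sd, s_meas)
        records.append(
            CohortRecord(
                episode_id=f"{'vvr' if is_vvr else 'normal'}-{i:03d}",
                trace=trace,
                truth="vvr" if is_vvr else "normal",
                drop_magnitude=mag,
                drop_time=t_drop,
                seed=s_draw,
            )
        )
    return records
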