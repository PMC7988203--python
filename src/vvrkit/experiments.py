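"""Reference in-silico experiments on the shipped parameter set.

Each function reruns one of the model's benchmark behaviours from
scratch: the baroreflex-sensitivity regressions under four vestibular /
noise conditions, and the drive-step response.  They are used by the
examples, the acceptance checks, and anyone wanting a one-call
reproduction of the reference behaviour.
"""

from __future__ import annotations

import numpy as np

from .beats import detect_systolic_peaks
from .brs import BRSResult, brs_regression
from .oscillator import (
    REFERENCE,
    REFERENCE_BPD,
    BPdSchedule,
    OscillatorParams,
    StimulusProfile,
    simulate,
)

__all__ = ["brs_slope_experiment", "BRS_CONDITIONS", "drive_step_experiment"]

#: The four benchmark conditions for the BRS regression.
BRS_CONDITIONS = ("noise_v0_0", "noise_v0_10", "noise_sinusoid", "no_noise")

_SKIP_S = 30.0  # discard the deterministic settling transient


def _constant_stimulus(level: float, duration: float) -> StimulusProfile:
    # constant otolith signal, realized as a full-duration 90-degree tilt
    return StimulusProfile(
        kind="tilt", amplitude=level, angle=90.0, onset=0.0, offset=duration
    )


def brs_slope_experiment(
    condition: str,
    seed: int = 0,
    params: OscillatorParams = REFERENCE,
    duration: float = 190.0,
) -> BRSResult:
    """BRS regression (ISI on previous systolic pressure) for one condition.

    Conditions: ``noise_v0_0`` (threshold noise, no vestibular input),
    ``noise_v0_10`` (constant V0 = 10), ``noise_sinusoid`` (V0 a
    low-frequency sinusoid of amplitude 10 at 0.025 Hz), ``no_noise``
    (sigma_T = 0; the regression is degenerate and the slope is 0).
    """
    if condition not in BRS_CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    p = params.with_(seed=seed)
    stim = None
    if condition == "no_noise":
        p = p.with_(sigma_T=0.0)
    elif condition == "noise_v0_10":
        stim = _constant_stimulus(10.0, duration)
    elif condition == "noise_sinusoid":
        stim = StimulusProfile(
            kind="sgvs", freq=0.025, amplitude=10.0, onset=0.0, offset=duration
        )
    trace = simulate(p, bpd=REFERENCE_BPD, stim=stim, duration=duration)
    n0 = int(_SKIP_S / p.dt)
    beats = detect_systolic_peaks(trace.t[n0:], trace.z2[n0:])
    return brs_regression(beats)


def drive_step_experiment(
    before: float = 50.0,
    after: float = 40.0,
    step_at: float = 15.0,
    duration: float = 30.0,
    params: OscillatorParams = REFERENCE,
) -> dict:
    """Drive-step response: pulse pressure, ISI and SBP before vs after.

    The benchmark VVR simulation: dropping the drive from 50 to 40 with
    the feedback threshold held at -100 shrinks the pulse pressure,
    lengthens the intersystolic interval (HR falls) and lowers the
    systolic level.
    """
    p = params.with_(sigma_T=0.0)
    tr = simulate(p, bpd=BPdSchedule.step(before, after, step_at), duration=duration)
    n0 = int(5.0 / p.dt)
    b = detect_systolic_peaks(tr.t[n0:], tr.z2[n0:])
    pre = b.peak_times < step_at - 0.5
    post = b.peak_times > step_at + 3.0
    pre_i = pre[:-1] & pre[1:]
    post_i = post[:-1] & post[1:]
    return {
        "pp_before": float(np.median(b.sbp[pre]) - np.median(b.dbp[pre])),
        "pp_after": float(np.median(b.sbp[post]) - np.median(b.dbp[post])),
        "isi_before": float(b.isi[pre_i].mean()),
        "isi_after": float(b.isi[post_i].mean()),
        "sbp_before": float(np.median(b.sbp[pre])),
        "sbp_after": float(np.median(b.sbp[post])),
    }
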