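"""Compiled inner loop of the relaxation-oscillator simulation.

The recurrence is strictly sequential (each step feeds the next), so it
cannot be vectorised; numba keeps cohort-scale simulation fast.
"""

import numpy as np
from numba import njit


@njit(cache=False)
def run_oscillator(
    dt: float,
    T: float,
    S: float,
    k: float,
    leak1: float,
    leak2: float,
    g_v: float,
    hp_a: float,
    f2_sat: float,
    f2_slope: float,
    h6: float,
    g2: float,
    bias: float,
    sigma_T: float,
    bpd: np.ndarray,
    v0: np.ndarray,
    noise: np.ndarray,
    x1_init: float,
    x2_init: float,
):  # pragma: no cover - exercised through oscillator.simulate
    n = bpd.shape[0]
    x1 = np.zeros(n)
    x2 = np.zeros(n)
    x2p = np.zeros(n)
    z2 = np.empty(n)
    x1[0] = x1_init
    x2[0] = x2_init

    Tt = T + sigma_T * noise[0]
    j = 1
    y_prev = 0.0  # high-pass filter output state, y[-1] = 0
    f2_prev = 0.0  # high-pass filter input state, x[-1] = 0

    for i in range(n):
        if i > 0:
            d = (x2[i] - x2[i - 1]) / dt
        else:
            d = 0.0
        f2v = f2_slope * d
        if f2v > f2_sat:
            f2v = f2_sat
        elif f2v < -f2_sat:
            f2v = -f2_sat
        y = hp_a * (y_prev + f2v - f2_prev)
        y_prev = y
        f2_prev = f2v
        if i > 0:
            x2p[i] = x2p[i - 1] + dt * y
        else:
            x2p[i] = dt * y
        z2[i] = h6 * x2p[i] + g2 * bpd[i] - bias

        if i < n - 1:
            u = k * (x2[i] - Tt)
            if u < 0.0:
                u = 0.0
            elif u > S:
                u = S
            x1[i + 1] = leak1 * x1[i] + dt * (bpd[i] + g_v * v0[i] - u)
            x2[i + 1] = leak2 * x2[i] + dt * x1[i]
            # redraw the stochastic threshold once per cycle, at the
            # diastole->systole transition (x2 turning point, x1 + -> -)
            if sigma_T > 0.0 and x1[i] > 0.0 and x1[i + 1] <= 0.0:
                Tt = T + sigma_T * noise[j]
                j += 1

    return x1, x2, x2p, z2
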