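# Methods

## The model

`vvrkit` implements a discrete-time, second-order relaxation oscillator
as a systems-level model of arterial blood pressure (BP) under central
and vestibular control, together with the beat-level analysis pipeline
used to detect and anticipate vasovagal responses (VVRs).

States `x1` and `x2` are coupled through unit-delay leaky integrators;
a piecewise-linear threshold/saturation element `f1` in the negative
feedback path switches the system between a slow (diastolic) and a fast
(systolic) phase:

    x1[n+1] = leak1*x1[n] + dt*(BP_d[n] + g_v*V0[n] - f1(x2[n]))
    x2[n+1] = leak2*x2[n] + dt*x1[n]
    f1(u)   = clip(k*(u - T), 0, S)

The measured pressure `z2` comes from a shaping path: the derivative of
`x2` passes through an odd saturating nonlinearity `f2`, a first-order
high-pass filter (cut-in 0.1 Hz, which keeps the downstream integrator
from drifting), and an integrator producing `x2p`:

    z2[n] = h6*x2p[n] + g2*BP_d[n] - bias

`BP_d` ("desired blood pressure") is the central drive that maintains
the oscillation.  Its level sets amplitude and period together, so a
drop in `BP_d` lowers systolic pressure and slows the beat at the same
time — this coordinated decline is the model's mechanism for a VVR.
Vestibular input `V0` (sinusoidal galvanic stimulation or tilt) enters
the same loop through `g_v`.  With `sigma_T > 0` the threshold `T` is
redrawn once per cycle (at the diastole-to-systole transition, i.e. the
pressure trough) from `N(T, sigma_T^2)`, producing beat-to-beat
variability in both systolic level and interval.

## The reference parameter set (and why each value)

Only the operating points `T = -100`, `BP_d = 50` (rest) and `40`
(during a VVR), the 0.1 Hz high-pass cut-in, and the 1 kHz sampling are
fixed by the source material; every other constant is a calibrated
reference value, chosen once against the published behaviours and then
frozen:

| parameter | value | role / rationale |
|---|---|---|
| `dt` | 1 ms | matches 1 kHz telemetric acquisition |
| `T` | -100 | feedback threshold (published) |
| `S` | 400 | saturation; `S >> 2*BP_d` makes the diastolic (sub-threshold) phase slow and the systolic phase fast, and makes the period sensitive to `BP_d` (about -10% ISI per +10 drive units) |
| `k` | 4e4 | steep linear region; with `leak1`, sets the instability that sustains the limit cycle |
| `leak1` | 0.996 | x1 damping; balances the growth so the cycle settles at a rat-like rate |
| `leak2` | 1.0 | pure integration of x2; keeps `BP_d` the controlling drive |
| `g_v` | -2.0 | vestibular gain; negative so vestibular activation inhibits the drive (tilt and sGVS push toward a VVR, and a constant `V0 = 10` *raises* the BRS slope as reported) |
| `f2_sat`, `f2_slope` | 6.0, 1.0 | `f2` is linear at cruise and clips only transients; full clipping inverts the amplitude-vs-drive relation and was rejected |
| `h6` | -300 | output gain; the sign makes the fast phase the systolic upstroke; magnitude sets pulse pressure ~42 mmHg |
| `g2`, `bias` | 3.5, 70.92 | map `BP_d = 50` to SBP 120 mmHg and make a 15% drive drop produce a >=25 mmHg systolic fall |
| `sigma_T` | 3e-4 | beat-to-beat ISI CV ~0.5% intrinsic; keeps noise-driven drops in normals far below the 25 mmHg / 25 bpm criterion while giving a stable, positive BRS regression |

At rest the reference configuration produces SBP 120 mmHg, DBP 78 mmHg,
pulse pressure 42 mmHg and HR 373 bpm — an anesthetized-rat operating
point.  Dropping `BP_d` from 50 to 40 lowers SBP by ~36 mmHg and HR by
~33 bpm.

A short self-test runs before every simulation: the parameter set must
sustain at least three cycles at the reference drive (`BP_d = 50`) or
`NonOscillatingError` is raised.  The probe tests the *parameter set*,
not the schedule, so simulating `BP_d = 0` legitimately returns a
decaying trace (the drive maintains the oscillation; without it the
output collapses to under 5% of the reference amplitude).

## Baroreflex-sensitivity behaviours

With threshold noise on, the regression of intersystolic interval (ISI)
on the previous systolic pressure has a positive slope; a constant
vestibular input `V0 = 10` raises it; a slow sinusoidal `V0` sweeps the
operating point along the drive curve, where amplitude and period move
oppositely, and the slope turns negative; with the noise off, the
orbit is strictly periodic, the regression is degenerate, and the slope
is 0 by convention.  All four signs and orderings reproduce the
published pattern (0.31, 0.6, -0.78, 0).

The printed *magnitudes* are not reproduced, and we believe they cannot
be in any configuration of this architecture that also satisfies the
25 mmHg / 25 bpm VVR criterion at rat heart rates.  Empirically, across
~1,500 random parameter sets, slope x pulse-pressure stays within a
factor of a few of r x ISI (the output path integrates the waveform, so
relative systolic fluctuations track relative interval fluctuations).
At ISI ~ 0.16 s this caps the slope near 0.01 s/mmHg for any detectable
pulse pressure; a slope of 0.31 would force a pulse pressure below
0.5 mmHg, unmeasurable under the 1 mmHg telemetry noise the cohort
generator emulates.  The parameter sets that break the coupling do so
by inverting the amplitude-vs-drive relation or zeroing the
period-vs-drive sensitivity, i.e. by destroying the VVR mechanism
itself.  The units of the published slopes are not stated; ours are
s per mmHg-equivalent.  We chose the configuration in which every
mechanistic behaviour holds and report the slope values it actually
produces (+0.0009, +0.0013, -0.010, 0).

## Beat analysis

Systolic peaks are strict local maxima with topographic prominence at
least `min_prominence` (default: 25% of the post-transient peak-to-peak
range), pruned greedily earliest-first with a 50 ms refractory period.
`dbp[i]` is the signal minimum between consecutive accepted peaks.  The
interval `isi[i]` *follows* systole `i` ("interval lags pressure"), and
`hr = 60/isi`.

The analysis pipeline (not the detector itself) preprocesses noisy
traces: a 25 ms boxcar before detection and a local-parabola sub-sample
refinement of each apex.  Without this, 1 mmHg sample noise jitters
peak times by several milliseconds, which dominates the beat-to-beat
interval differences the dBRS metric is built from.

Episode drop features use a robust baseline (median over a pre-stimulus
window, default 60 s) and the minimum over the response window; drops
are clamped at zero.  The joint VVR criterion is inclusive:
`bp_drop >= 25 mmHg AND hr_drop >= 25 bpm`.

## dBRS, the polynomial derivative, and Tvvr

The instantaneous BRS series is the moving mean over the last `W`
retained ratios `(isi[i]-isi[i-1])/(sbp[i]-sbp[i-1])`, where ratios
with `|dSBP| < eps` are excluded (and counted) so near-zero
denominators cannot dominate.  Library defaults are `W = 5`,
`eps = 0.5 mmHg`; the pipeline's analysis configuration uses `W = 1`
with `eps = 2.5 mmHg` — at the reference noise level the polynomial
stage is the better smoother, and the guard keeps only increments well
above the noise floor of the pressure differences.

A degree-`d` polynomial (Chebyshev-rescaled abscissa; library default
8, pipeline 16) is fitted to the series, differentiated analytically
(domain chain rule included), and scanned on a dense grid for the
earliest crossing of `Tvvr` (default direction: downward, since during
a VVR interval rises while pressure falls).  The drop onset is the
first post-baseline beat whose SBP falls below the baseline median
minus half the full excursion (`drop_fraction = 0.5`).

The shipped `Tvvr = -1e-4` is sensitivity-oriented: on synthetic VVR
episodes the crossing precedes the systolic-drop onset in >= 98% of
traces, typically by a wide margin (it often fires early in the
record).  It makes no specificity claim — on a quiet trace the fitted
derivative can cross the threshold without any VVR.  A green onset
test therefore establishes anticipation, not discrimination.

## The synthetic cohort: what it emulates, what it does not

Each episode is 150 s at 1 kHz: 70 s of rest, then low-frequency sGVS
(0.025 Hz, amplitude 1.5) to the end.  VVR episodes additionally drop
the drive by 15-30% of its resting level (the published VVR simulation
drops it by 20%) at a uniform random time in 80-110 s, as a 1-s linear
ramp — a drive drop develops over a short but nonzero time, and the
ramp keeps consecutive beats coherently coordinated instead of exciting
a single anomalous transition beat.  Gaussian noise of 1 mmHg (typical
of implanted telemetry) is added to the pressure output only.  All
randomness derives from one seed via independent spawned streams, so
cohorts are exactly reproducible.

The generator emulates: triangular systolic/diastolic waves at rat
rates, beat-to-beat variability from threshold noise, stimulus-locked
HR modulation, and mechanistic coordinated BP+HR drops.  It does not
emulate: movement artifacts, telemetry dropouts, ectopic beats,
habituation across sessions, baseline differences between animals, or
a VVR probability that depends on stimulus frequency.  Consequently the
two truth classes separate perfectly in BPmaxdrop (VVR drops >= ~26
mmHg by construction, normals ~6 mmHg under noise), so a green
classifier test shows the seed-label-then-discriminate machinery works,
not that the two-feature boundary beats a pressure threshold on
overlapping data — on this cohort they tie.

## Numerical choices

* Inner loop compiled with numba; one threshold draw per step is
  pre-allocated as a safe upper bound on per-cycle redraws, keeping the
  generator outside the compiled code and results bit-reproducible.
* High-pass filter: `y[n] = a (y[n-1] + x[n] - x[n-1])`,
  `a = tau/(tau+dt)`, `tau = 1/(2 pi fc)`, zero initial conditions.
* The deterministic orbit settles to ~1e-11 systolic variation after
  ~30 s; analyses discard at least the first 10 s (30 s for the BRS
  benchmark runs).  Degenerate regression threshold: SBP variance
  below 1e-12.
* Hyperplane: margin perceptron (margin 0.1, rate 0.1, deterministic
  pass order) on per-feature standardized data, with a least-squares
  discriminant fallback after 1e4 epochs when inseparable.  Boundary
  ties classify as VVR (fail-safe toward detection).  No self-training
  after the single seed-label pass.
* Beat detection on plateaus follows the SciPy convention (plateau
  midpoint); simulated and noisy data have no exact plateaus.
* CSV readers use round-trip float parsing so write/read cycles are
  exact.

## Known limitations

* The published BRS slope magnitudes are not reproduced (see above);
  signs, orderings and the degenerate case are.
* The published real-rat data points (hyperplane figure, onset figure)
  are not tabulated in the source, so classifier and onset behaviour
  are validated only on the synthetic world.
* `Tvvr` as shipped is a sensitive but unspecific alarm.
* The drive-drop ramp time (1 s) and the episode layout are modeling
  choices of the generator, stated here and fixed; they were not fitted
  to data.
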