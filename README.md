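# vvrkit

Modeling and detection of **vasovagal responses (VVRs)** — transient,
coordinated drops in blood pressure and heart rate that underlie
vasovagal syncope (fainting).  `vvrkit` is aimed at computational
physiologists working with continuous arterial-pressure recordings
(e.g. telemetric recordings from rodents under vestibular stimulation)
who want a mechanistic simulator of the systolic/diastolic oscillation
and a beat-level pipeline that identifies VVRs from features richer
than a bare pressure threshold.

## What is inside

**A relaxation-oscillator model of BP.**  A second-order discrete
oscillator with states x1, x2, a threshold/saturation feedback element
f1(u) = clip(k(u−T), 0, S), and a central drive BP_d that maintains the
oscillation.  The pressure output is
z2 = h6·x2p + g2·BP_d − bias, where x2p integrates the high-pass
filtered (0.1 Hz), nonlinearly shaped derivative of x2.  The model's
key property: a drop in BP_d lowers systolic pressure *and* lengthens
the beat interval simultaneously — the VVR mechanism.  Vestibular input
V0 (sGVS or tilt) enters the loop through a gain g_v, and per-cycle
Gaussian perturbation of the threshold T produces realistic
beat-to-beat variability.

**Baroreflex-sensitivity (BRS) metrics.**  The classic BRS regression
(intersystolic interval vs. previous systolic pressure), the
instantaneous variant ΔBRS — a moving window over beat-to-beat ratios
Δ(ISI)/Δ(SBP) — and onset prediction: a polynomial fit to ΔBRS is
differentiated analytically and the first crossing of a threshold
T_vvr anticipates the systolic drop.

**A seed-labeled linear classifier.**  Episodes are points in
(BPmaxdrop, |ΔBRS|max) space; unambiguous extremes of BPmaxdrop are
seed-labeled, a separating hyperplane is learned from the seeds (margin
perceptron with a least-squares fallback), and the rest are classified
— compared against the conventional 25 mmHg (and 18 mmHg) single
thresholds.

**A mechanistic synthetic-cohort generator.**  Labeled normal/VVR
episodes produced by the simulator itself (drive drops through the
dynamics, sGVS stimulation, telemetry noise), exactly reproducible from
one seed, so the full pipeline is testable without any recording.

## Worked example

```python
import numpy as np
from vvrkit import BPdSchedule, REFERENCE, detect_systolic_peaks, simulate

trace = simulate(REFERENCE.with_(sigma_T=0.0), bpd=50.0, duration=30.0)
skip = int(10 / trace.dt)
beats = detect_systolic_peaks(trace.t[skip:], trace.z2[skip:])
print(np.median(beats.sbp), np.median(beats.dbp), 60 / beats.isi.mean())
```

prints (reference configuration at rest):

```
120.00425912035763 77.67391117336078 372.67080745341616
```

i.e. systolic 120 mmHg, diastolic 78 mmHg, heart rate 373 bpm — an
anesthetized-rat operating point.  Dropping the drive mid-run
(`BPdSchedule.step(50, 40, 15.0)`) lowers systolic pressure to 84.5
mmHg and the rate to 340 bpm: pressure and rate fall together, which is
what defines a VVR in this model.

The `examples/` directory has one short script per capability:

| script | shows |
|---|---|
| `01_simulate_pressure_waves.py` | resting waves; the drive-drop VVR mechanism |
| `02_brs_regressions.py` | BRS slopes under four vestibular/noise conditions |
| `03_cohort_classification.py` | cohort → features → hyperplane vs. thresholds |
| `04_onset_prediction.py` | ΔBRS derivative, T_vvr crossing, lead times |

Each prints the numbers it computes and one or two lines on what they
mean.  `docs/methods.md` documents the model, every tunable parameter
with units and rationale, the calibration of the reference set, and
known limitations (including which published quantities the reference
configuration does and does not reproduce).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's benchmark computations from scratch with the
given seed: the four BRS regression experiments on freshly simulated
traces, the drive-step response, a full synthetic-cohort
generate→detect→classify pass, and onset detection on a VVR episode.
It prints a summary of what it computed and writes the results file.
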