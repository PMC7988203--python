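"""Classify a synthetic cohort of normal and VVR episodes.

Generates 10 VVR and 10 normal episodes mechanistically (drive drops
through the oscillator plus telemetry noise), extracts the two episode
features — the maximal systolic-pressure drop (BPmaxdrop) and the
maximal instantaneous-BRS excursion (|dBRS|max) — seed-labels only the
unambiguous extremes, learns a separating hyperplane from the seeds,
classifies the rest, and compares against the conventional 25 mmHg and
18 mmHg single-threshold rules.
"""

from vvrkit import CohortSpec, generate_cohort, run_vvr_pipeline

spec = CohortSpec(n_vvr=10, n_normal=10, seed=7)
records = generate_cohort(spec)
predicted, truth, plane, report = run_vvr_pipeline(records, spec)

print("episode        truth    predicted   BPmaxdrop   |dBRS|max")
for p, t in zip(predicted, truth):
    print(f"{p.episode_id:12s} {t.label:8s} {p.label:10s} "
          f"{p.bp_max_drop:8.1f}    {p.delta_brs_max:8.4f}")

hp = report.hyperplane
print(f"\nhyperplane:   {hp.errors} errors "
      f"(tp={hp.tp} tn={hp.tn} fp={hp.fp} fn={hp.fn}), "
      f"training error {plane.train_error:.2f}")
for thr, c in report.baselines.items():
    print(f"threshold {thr:4.0f} mmHg: {c.errors} errors "
          f"(missed VVRs = {c.fn}, false alarms = {c.fp})")
print("\nThe learned boundary combines pressure and baroreflex information.")
print("On this synthetic cohort the classes separate cleanly in BPmaxdrop, so")
print("the single-threshold rules tie; on real recordings, where drop sizes")
print("overlap, thresholds trade missed VVRs against false alarms while the")
print("two-feature boundary can use the dBRS axis to split the ambiguous band.")
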