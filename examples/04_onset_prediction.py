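"""Predict VVR onset from the derivative of the fitted dBRS series.

For one synthetic VVR episode: extract beats, build the instantaneous
baroreflex-sensitivity series (beat-to-beat interval/pressure ratios),
fit a polynomial, differentiate it analytically, and report when the
derivative first crosses the shipped threshold Tvvr relative to when
systolic pressure actually starts to fall.
"""

from vvrkit import CohortSpec, generate_cohort
from vvrkit.pipeline import TVVR_DEFAULT, episode_onset

spec = CohortSpec(n_vvr=3, n_normal=0, seed=21)
records = generate_cohort(spec)

print(f"shipped Tvvr = {TVVR_DEFAULT} (downward crossing of d(dBRS)/dt)\n")
for rec in records:
    res = episode_onset(rec, spec)
    print(f"{rec.episode_id}: drive drop injected at t = {rec.drop_time:.1f} s")
    print(f"   Tvvr crossing at      t = {res.crossing_time:.1f} s")
    print(f"   systolic drop onset   t = {res.bp_drop_onset_time:.1f} s")
    print(f"   lead time             {res.lead_time:+.1f} s")

print("\nA positive lead time means the baroreflex metric fires before the")
print("pressure drop is visible.  The shipped threshold favors sensitivity:")
print("it fires early, and on quiet traces it can fire without a VVR.")
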