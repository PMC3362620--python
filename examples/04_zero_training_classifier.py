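"""Zero-training classification with a resting-power baseline.

Simulates a hemispherically asymmetric subject (right motor rhythm three
times stronger than the left), learns spatial filters from rest only, and
compares the raw sign rule (larger motor-component power wins) with the
baseline-weighted rule that divides each trial power by the component's
mean resting power before comparing.
"""

from rest2task import SimConfig, default_scene, simulate_session
from rest2task.decomposition import apply_filters, decompose_state
from rest2task.forward import default_montage
from rest2task.io import state_segments
from rest2task.motor_ic import canonical_motor_template, select_motor_ics
from rest2task.pipeline import rest_baseline, zero_training_accuracy

labels, pos = default_montage()
cfg = SimConfig(default_scene(right_motor_amplitude=18.0),
                n_trials_per_class=60, seed=7)
ts, _ = simulate_session(cfg)

X = state_segments(ts, "rest")
dec = decompose_state(X, seed=7)
tc = apply_filters(dec, X)
tc.fs = ts.fs
sel = select_motor_ics(dec, tc, canonical_motor_template(labels, pos), pos)

base = rest_baseline(ts, dec, sel)
print(f"resting baseline power: left IC {base.mu_left:.1f}, "
      f"right IC {base.mu_right:.1f} (ratio {base.mu_right / base.mu_left:.1f}x)")
print(f"raw sign rule:       {zero_training_accuracy(ts, dec, sel, weighted=False):.1f}%")
print(f"baseline-weighted:   {zero_training_accuracy(ts, dec, sel, weighted=True):.1f}%")

print("\nWithout the baseline the stronger right hemisphere dominates almost "
      "every trial and the sign rule collapses toward chance; dividing by "
      "each component's resting power cancels the asymmetry, so the rule "
      "needs no labeled calibration data at all.")
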