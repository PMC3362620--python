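"""Simulate a motor-imagery EEG session and inspect its ground truth.

Builds the default four-source scene (left/right sensorimotor mu+beta,
posterior alpha, frontal low-frequency artifact), generates a short
session, and verifies the contralateral ERD directly on the true source
time courses.
"""

import numpy as np

from rest2task import SimConfig, default_scene, simulate_session

cfg = SimConfig(default_scene(), n_trials_per_class=40, seed=0)
ts, truth = simulate_session(cfg)

print(f"session: {ts.n_trials} trials x {ts.trials.shape[1]} channels "
      f"x {ts.trials.shape[2]} samples at {ts.fs:.0f} Hz")
print(f"sources: {', '.join(truth.source_names)}")

# project sensor data onto the true unmixing row of the right motor source
w = np.linalg.pinv(truth.mixing)[truth.source_names.index("motor_right")]
src = np.einsum("c,tcs->ts", w, ts.trials)
a, b = ts.window_samples("rest")
c, d = ts.window_samples("imagery")
for label in ("left", "right"):
    sel = ts.labels == label
    ratio = (src[sel, c:d] ** 2).mean() / (src[sel, a:b] ** 2).mean()
    print(f"right motor source, {label}-hand trials: imagery/rest power = {ratio:.2f}")

print("\nThe right motor source loses ~3/4 of its power during left-hand "
      "imagery (contralateral ERD at depth -0.5 scales amplitude by 0.5) and "
      "gains slightly during right-hand imagery (ipsilateral ERS, +0.15).")
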