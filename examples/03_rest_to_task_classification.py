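"""Full rest-to-task comparison on one simulated subject.

Trains ICA separately on the resting and imagery windows, identifies the
motor components automatically, and cross-validates FDA classification of
left- vs right-hand imagery with four feature sets: raw C3/C4 band power,
imagery-trained ICA filters, rest-trained ICA filters (the zero-training
translation), and fold-trained CSP.
"""

from rest2task import RunConfig, SimConfig, default_scene, simulate_session
from rest2task.pipeline import cross_state_similarity, run_rest_to_task

cfg = SimConfig(default_scene(), n_trials_per_class=60, seed=42)
ts, _ = simulate_session(cfg)
result = run_rest_to_task(ts, cfg=RunConfig(cv_repetitions=3, seed=42))

print(result.report.to_string(index=False))

sim = cross_state_similarity(result.dec_rest, result.dec_imagery,
                             result.selection_rest, result.selection_imagery)
print("\ncross-state similarity of the selected motor components:")
print(sim.round(3).to_string(index=False))

print("\nThe rest-trained spatial filters — learned without a single imagery "
      "sample or label — classify within a few points of the imagery-trained "
      "filters, and every spatial-filter method beats the monopolar C3/C4 "
      "baseline, whose band power is contaminated by the posterior alpha "
      "rhythm.  Pattern correlations near 1 show why the translation works: "
      "the motor sources' scalp projections are the same in both states.")
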