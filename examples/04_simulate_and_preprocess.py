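"""A full synthetic experiment through the preprocessing pipeline.

Simulates the blocked gaze-contingent search design (16 subjects x 4 blocks
x 100 trials, target present in half, mirrored layouts, planted nuisance
failures), applies the sequential trial filters, and contrasts the first
fixation between the short and long conditions with Hotelling's T^2.
"""

import numpy as np

from gazeplan import ModelSpec, SimConfig, hotelling_t2, simulate_experiment
from gazeplan.behavior import filter_trials, summarize_subjects
from gazeplan.shapes import select_stimuli

spec = ModelSpec(policy="planned", horizon=2)
shapes, reports, _ = select_stimuli(seed=11, spec=spec,
                                    n_divergent=1, n_coincident=1)

cfg = SimConfig(seed=0)  # planning generator, alpha=0.3, u=0.03 by default
ds = simulate_experiment(cfg, shapes)
kept, rep = filter_trials(ds.trials)

print(f"trials entering preprocessing: {rep.n_input}")
print(f"  no gaze on shape : {rep.n_no_shape_gaze:5d} "
      f"({rep.pct_no_shape_gaze:5.2f}% of input)")
print(f"  wrong fix count  : {rep.n_wrong_fixation_count:5d} "
      f"({rep.pct_wrong_fixation_count:5.2f}% of remaining)")
print(f"  target present   : {rep.n_target_present:5d} "
      f"({rep.pct_target_present:5.2f}% of remaining)")
print(f"  analyzed         : {rep.n_final:5d}\n")

summary = summarize_subjects(kept)
for shape, r in zip(shapes, reports):
    a = summary.observations((shape.shape_id, "short", 1))
    b = summary.observations((shape.shape_id, "long", 1))
    h = hotelling_t2(a, b)
    print(f"{shape.shape_id:15s} short vs long first fixation: "
          f"T2 = {h.t2:8.2f}, p = {h.p_value:.2e}")

print("\nUnder a planning generator the first fixation shifts with the")
print("available search time on the divergent shape (enormous T2), while")
print("on the coincident shape the statistic stays at the scale expected")
print("under the null.")
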