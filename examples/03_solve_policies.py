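"""Greedy vs. planned gaze policies on a toy shape.

A plus-shaped region of 49 unit cells, searched with a 6.5-deg circular
window.  The greedy (myopic) observer grabs the arm intersection first; the
planner accepts a worse first fixation to cover strictly more of the shape
with the full two-fixation sequence — the mountain-car logic of gaze.
"""

import numpy as np

from gazeplan import (
    ModelSpec,
    detection_probability,
    solve_map,
    solve_myopic,
    solve_planned,
    target_prior,
)
from gazeplan.shapes import ShapeGrid

mask = np.zeros((25, 25), dtype=np.uint8)
mask[12, :] = 1
mask[:, 12] = 1
plus = ShapeGrid(mask=mask, cell_size_deg=1.0, x0=-12.0, y0=-12.0,
                 shape_id="plus")
belief = target_prior(plus)
spec = ModelSpec(policy="planned", horizon=2, start_location=(-14.0, 0.0))

greedy = solve_myopic(plus, ModelSpec(policy="myopic", horizon=2,
                                      start_location=(-14.0, 0.0)))
planned = solve_planned(plus, spec)
mapper = solve_map(plus, ModelSpec(policy="map", horizon=2,
                                   start_location=(-14.0, 0.0)))

dp1 = detection_probability(belief, [greedy.planned_targets[0]], 6.5)
print(f"greedy  fixations {greedy.planned_targets.tolist()}  "
      f"first covers {dp1:.4f} (= 25/49), total {greedy.detection_prob:.4f}")
print(f"planned fixations {planned.planned_targets.tolist()}  "
      f"total {planned.detection_prob:.4f}")
print(f"MAP     fixations {mapper.planned_targets.tolist()}  "
      f"total {mapper.detection_prob:.4f}")
print(f"\nplanning gain over greedy: "
      f"{planned.detection_prob - greedy.detection_prob:+.4f} detection"
      " probability")
print("The greedy first fixation individually covers the most cells, but the")
print("planned pair of fixations covers more of the shape overall.")
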