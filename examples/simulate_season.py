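"""Simulate a wood-formation season and look at the ground truth.

The built-in scenario has three treatment groups of five maritime-pine-like
trees: control (41 tracheids, bimodal production), irrigation (30,
bimodal), and rain exclusion (26, unimodal), censused every 10 days.
"""

import numpy as np

from xylokin import average_radial_files, default_paper_scenario
from xylokin.synthetic import observe_counts, simulate, truth_to_frame

sim = simulate(default_paper_scenario(seed=2017))
truth = truth_to_frame(sim)

print("true cells per tree:")
print(truth.groupby(["group", "tree_id"]).size().to_string())

first = truth[truth["cell_index"] == 1]
print("\nfirst cell entered enlargement on season day (per group):")
print(first.groupby("group")["t_enl"].mean().round(1).to_string())

obs = observe_counts(sim)
counts = average_radial_files(obs)
print(f"\n{len(obs)} census records -> {len(counts)} per-tree per-day means")
print("(phase counts are means over 3 radial files, so fractions are expected)")
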