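"""Fit seasonal phase-count curves and compare treatments by band overlap.

Each group x phase gets a penalized cubic spline with a random intercept
per tree; groups differ significantly wherever the pointwise 95% bands are
disjoint.
"""

import numpy as np

from xylokin import (
    average_radial_files,
    compare_groups,
    default_paper_scenario,
    fit_group_phase_curves,
)
from xylokin.phenology import phenology_metrics
from xylokin.synthetic import observe_counts, simulate

sim = simulate(default_paper_scenario(seed=2017))
counts = average_radial_files(observe_counts(sim))
curves = fit_group_phase_curves(counts)

print("fitted curve peaks (cells):")
for (group, phase), c in sorted(curves.items()):
    print(f"  {group:10s} {phase:10s} max={c.mean.max():5.1f}  edf={c.edf:4.1f}")

w = compare_groups(curves[("control", "mature")], curves[("exclusion", "mature")])
print("\ncontrol vs exclusion, mature cells — significant on season days:")
for start, end in w.windows:
    print(f"  [{start:.0f}, {end:.0f}]  (bands disjoint: control formed more wood)")

print("\nwall-deposition phenology (onset/cessation at the half-cell rule):")
for group in ("control", "irrigation", "exclusion"):
    m = phenology_metrics(curves[(group, "thickening")])
    peaks = ", ".join(f"{d:.0f}" for d in m.peak_days)
    print(
        f"  {group:10s} {m.modality:8s} peaks at day(s) {peaks}; "
        f"active {m.onset_day:.0f}-{m.cessation_day:.0f}"
    )
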