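"""Standardize tracheidograms to relative ring position and compare groups.

Rings with different cell numbers are put on a common (0,1) axis by
dividing each tracheid's center distance by the ring width; trait curves
over that axis are then compared by confidence-band overlap, and earlywood
and latewood are separated by Mork's index (latewood iff 4 CWT >= LD).
"""

from xylokin.core import TracheidRecord
from xylokin.pipeline import _tracheids_with_relpos
from xylokin.synthetic import default_paper_scenario, simulate, tracheids_from_cohort
from xylokin.tracheidogram import (
    compare_trait_profiles,
    earlywood_latewood_split,
    relative_positions,
)

sim = simulate(default_paper_scenario(seed=2017))
anat = tracheids_from_cohort(sim)
records = [
    TracheidRecord(r.tree_id, r.group, r.radial_file, r.cell_index,
                   r.lumen_diameter, r.wall_thickness)
    for r in anat.itertuples(index=False)
]

print("earlywood / latewood split (Mork's index), one tree per group:")
for group in ("control", "irrigation", "exclusion"):
    cells = [r for r in records if r.group == group and r.tree_id.endswith("t1")]
    ew, lw = earlywood_latewood_split(relative_positions(cells))
    print(f"  {group:10s} {ew:2d} earlywood + {lw:2d} latewood = {ew + lw} cells")

df = _tracheids_with_relpos(records)
_, windows = compare_trait_profiles(df, "wall_thickness")
print("\nwall-thickness differences along the ring (rel_pos windows):")
for w in windows:
    pair = " vs ".join(w.group_pair)
    if w.windows:
        spans = ", ".join(f"[{a:.2f}, {b:.2f}]" for a, b in w.windows)
        print(f"  {pair}: bands disjoint on {spans}")
    else:
        print(f"  {pair}: no significant stretch")
print(
    "(exclusion walls run thinner across the ring; note that noiseless\n"
    " synthetic anatomy gives very tight bands, so even small gaps register)"
)
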