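"""Shear trends across gestation: the central homeostasis analysis.

Runs the full stage sweep and reports:

* the per-vessel trend table (AAo, DAo, PT+ductus means per stage),
* Pearson/regression statistics of shear stress, shear rate, centerline
  velocity and lumen area against age and against vessel size,
* the Murray's-law validation (simulated vs measured branch velocities,
  exact Mann-Whitney per age and artery),
* an unwrapped wall-shear map of the aorta with ostial holes,
* the maximum centerline-averaged Reynolds number (laminar regime check).

The headline: velocities and lumen areas rise strongly with age while
vessel-mean wall shear stays nearly level — the shear-homeostasis signature.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from fetalshear.blood import blood_at_age
from fetalshear.sweep import run_stage_sweep
from fetalshear.wallshear import unwrap_map, wall_shear

SEED = 20140127
OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

res = run_stage_sweep(seed=SEED)
res.trend_table.to_csv(OUT / "trend_table.csv", index=False)
res.trend_stats.to_csv(OUT / "trend_stats.csv", index=False)
res.murray_validation.to_csv(OUT / "murray_validation.csv", index=False)

# unwrapped shear map of the near-term aortic path (root -> DAo outlet),
# with holes at the three head-and-neck ostia
cfg = res.configs[-1]
from fetalshear.tree import BRANCH_THETAS, generate_vessel_tree

tree = generate_vessel_tree(cfg)
props = blood_at_age(cfg.age_days, cfg)
net = res.networks[cfg.age_days]
aorta_edges = net[net.edge.isin(["aao_root", "aao_mid1", "aao_mid2", "isthmus", "dao"])].copy()
# lay the edges end-to-end along the aortic path
offsets = {}
s0 = 0.0
for name in ["aao_root", "aao_mid1", "aao_mid2", "isthmus", "dao"]:
    offsets[name] = s0
    s0 += float(aorta_edges.loc[aorta_edges.edge == name, "length_mm"].iloc[0])
wsf = wall_shear(aorta_edges, props)
wsf.samples["arclength_mm"] = [
    offsets[e] + s for e, s in zip(wsf.samples.segment, wsf.samples.arclength_mm)
]
arch_scale = tree.scale * 0.65
holes = [
    (arch_scale * np.deg2rad(BRANCH_THETAS[nm]), 0.0, tree.outlet_nodes[f"out_{nm}"])
    for nm in BRANCH_THETAS
]
umap = unwrap_map(wsf, holes=holes)
np.savetxt(OUT / "unwrapped_shear_map_E18.5.csv", umap.values, delimiter=",",
           header="tau_mPa grid: rows=arclength, cols=azimuth; NaN = ostial hole")

summary = dict(
    max_centerline_Re=res.max_Re,
    tau_relative_spread=res.tau_relative_spread(),
    area_growth_factor=res.area_growth_factor(),
    min_murray_p=float(res.murray_validation.p_value.min()),
    unwrapped_map_holes=int(umap.holes),
    unwrapped_map_mean_tau_mPa=umap.masked_mean(),
)
(OUT / "trend_summary.json").write_text(json.dumps(summary, indent=1))

print("Per-vessel trend table (means at peak flow):")
print(res.trend_table.round(2).to_string(index=False))
print("\nTrend statistics (pooled over vessels):")
print(res.trend_stats.round(4).to_string(index=False))
print("\nMurray validation (exact Mann-Whitney, simulated vs measured):")
print(res.murray_validation.round(3).to_string(index=False))
print(f"\nMax centerline-averaged Re across vessels and stages: {res.max_Re:.1f} "
      f"(laminar, viscous-dominated).")
print(f"Vessel-mean wall shear varies only {100*res.tau_relative_spread():.1f}% across "
      f"stages while mean lumen area grows {res.area_growth_factor():.1f}-fold — the "
      f"shear-homeostasis signature.")
print(f"Unwrapped aortic shear map: {umap.holes} ostial holes, "
      f"masked-mean tau {umap.masked_mean():.0f} mPa.")
print(f"Wrote trend tables, statistics and map to {OUT}")
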