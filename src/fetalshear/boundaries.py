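"""Flow boundary conditions: Murray's-law outlet splits and plug inlets.

The measured quantity is the peak descending-aorta velocity V(t).  Assuming a
parabolic profile there, the DAo volumetric flow is Q = V * pi R^2 / 2 (mean
velocity is half the peak).  Murray's law — flow scales with the cube of
vessel radius — then fixes every outlet's share of total flow, and the two
root inlets are given equal plug velocities whose combined inflow balances the
outflow exactly, matching the ultrasound observation that aortic-root and
pulmonary-root velocities are the same.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .tree import VesselTree
from .velocity import VelocityAgeModel


def murray_fractions(outlet_radii) -> np.ndarray | dict:
    """Flow fraction per outlet: r_i^3 / sum_j r_j^3.

    Accepts a sequence of radii (returns an array) or a dict name->radius
    (returns a dict with the same keys).
    """
    if isinstance(outlet_radii, dict):
        keys = list(outlet_radii)
        fr = murray_fractions([outlet_radii[k] for k in keys])
        return dict(zip(keys, fr))
    r = np.asarray(outlet_radii, dtype=float)
    if r.size == 0:
        raise ValueError("empty outlet list")
    if np.any(r <= 0):
        raise ValueError("all outlet radii must be positive")
    cubes = r**3
    return cubes / cubes.sum()


@dataclass(frozen=True)
class FlowBoundarySet:
    """Assembled inlet/outlet conditions for one stage, units mm and s."""

    inlet_velocities: dict        # node -> plug velocity, mm/s (all equal)
    inlet_radii: dict             # node -> radius, mm
    outlet_fractions: dict        # node -> fraction of total flow
    outlet_flows: dict            # node -> volumetric flow, mm^3/s
    outlet_peak_velocities: dict  # node -> parabolic peak velocity, mm/s
    total_flow: float             # mm^3/s
    age_days: float
    dao_peak_velocity: float      # mm/s

    def inlet_flow(self) -> float:
        return sum(
            v * math.pi * self.inlet_radii[k] ** 2 for k, v in self.inlet_velocities.items()
        )

    def outlet_flow(self) -> float:
        return sum(self.outlet_flows.values())


def assemble_boundaries(
    tree: VesselTree, model: VelocityAgeModel | float, age_days: float | None = None
) -> FlowBoundarySet:
    """Build the stage's boundary set from the velocity-age model and the tree.

    ``model`` may also be a plain peak DAo velocity in mm/s.  The descending
    aorta anchors the total flow; every other outlet follows Murray's law; the
    two roots get equal plug velocities balancing inflow and outflow.
    """
    if age_days is None:
        age_days = tree.config.age_days
    v_dao = float(model(age_days)) if callable(model) else float(model)
    if v_dao <= 0:
        raise ValueError(f"non-positive DAo peak velocity {v_dao} at age {age_days}")

    outlets = tree.outlet_radii()
    if "out_descending_aorta" not in outlets or len(outlets) < 2:
        raise ValueError("tree must have a descending-aorta outlet and >= 1 other outlet")
    if any(r <= 0 for r in outlets.values()):
        raise ValueError("outlet with non-positive radius")

    r_dao = outlets["out_descending_aorta"]
    q_dao = v_dao * math.pi * r_dao**2 / 2.0   # parabolic: mean = peak/2
    fractions = murray_fractions(outlets)
    total = q_dao / fractions["out_descending_aorta"]
    flows = {k: f * total for k, f in fractions.items()}
    peaks = {k: 2.0 * q / (math.pi * outlets[k] ** 2) for k, q in flows.items()}

    inlet_area = sum(math.pi * r**2 for r in tree.inlet_nodes.values())
    v_plug = total / inlet_area
    inlet_velocities = {k: v_plug for k in tree.inlet_nodes}

    bc = FlowBoundarySet(
        inlet_velocities=inlet_velocities,
        inlet_radii=dict(tree.inlet_nodes),
        outlet_fractions=fractions,
        outlet_flows=flows,
        outlet_peak_velocities=peaks,
        total_flow=total,
        age_days=age_days,
        dao_peak_velocity=v_dao,
    )
    assert abs(bc.inlet_flow() - bc.outlet_flow()) <= 1e-9 * bc.total_flow
    return bc
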