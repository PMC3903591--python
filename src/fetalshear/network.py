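"""Reduced-order Poiseuille network solution on the great-artery tree.

At the Reynolds numbers of the fetal great arteries (< 30) viscous forces
dominate, so each vessel segment is well described by fully developed
Poiseuille flow: pressure drop dp = 8 mu L Q / (pi R^4), wall shear stress
tau = 4 mu Q / (pi R^3), peak velocity 2 Q / (pi R^2).  Flows are imposed by
the boundary set (Murray outlet fractions, equal root plug inflows) and
propagated through the network with exact mass balance at every junction.

On a Murray-consistent tree (Q proportional to R^3 on every segment)
tau = 4 mu k / pi is the same on every segment — the network-level statement
of shear constancy.
"""

from __future__ import annotations

import math

import networkx as nx
import pandas as pd

from .blood import BloodProperties
from .boundaries import FlowBoundarySet
from .tree import VesselTree

FLOW_TOL = 1e-9


def solve_poiseuille_network(
    tree: VesselTree, bc: FlowBoundarySet, props: BloodProperties
) -> pd.DataFrame:
    """Per-segment flow, velocities, pressure drop and wall shear.

    Returns a DataFrame with one row per flow edge: ``edge, group, node_u,
    node_v, radius_mm, length_mm, Q_mm3_s, V_mean_mm_s, V_max_mm_s, dp_Pa,
    tau_mPa, gamma_per_s``.  Raises if junction mass balance cannot be
    satisfied with the imposed boundary flows.
    """
    g = nx.DiGraph()
    for e in tree.flow_edges():
        g.add_edge(e.node_u, e.node_v, edge=e)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("flow network must be loop-free")

    # demanded flow of a subtree below an edge: sum of outlet flows reachable
    # *without* passing through a merge node fed by another inlet; here the only
    # merge is the DAo junction, handled by the remainder rule below.
    inflow = {n: 0.0 for n in g.nodes}
    for node, v in bc.inlet_velocities.items():
        inflow[node] += v * math.pi * bc.inlet_radii[node] ** 2

    outlet_demand = dict(bc.outlet_flows)

    def subtree_outlets(node) -> list[str]:
        return [n for n in nx.descendants(g, node) | {node} if n in outlet_demand]

    flows: dict[str, float] = {}
    for node in nx.topological_sort(g):
        avail = inflow[node]
        out_edges = list(g.out_edges(node, data=True))
        if not out_edges:
            # terminal outlet: check imposed demand was met
            if node in outlet_demand and abs(avail - outlet_demand[node]) > 1e-6 * max(
                bc.total_flow, 1.0
            ):
                raise ValueError(
                    f"flow-assignment inconsistency at outlet {node}: "
                    f"arriving {avail:.6g}, demanded {outlet_demand[node]:.6g}"
                )
            continue
        # edges whose subtree is a pure outlet subtree get their demand; at most
        # one remaining ("through") edge absorbs the remainder
        demands = []
        through = None
        for _, vtx, data in out_edges:
            sub = subtree_outlets(vtx)
            reachable_from_elsewhere = any(
                g.in_degree(m) > 1 for m in nx.descendants(g, vtx) | {vtx}
            )
            if reachable_from_elsewhere:
                if through is not None:
                    raise ValueError(f"ambiguous flow split at junction {node}")
                through = data["edge"]
                demands.append((data["edge"], None))
            else:
                q = sum(outlet_demand[m] for m in sub)
                demands.append((data["edge"], q))
        assigned = sum(q for _, q in demands if q is not None)
        rem = avail - assigned
        if through is None and abs(rem) > 1e-6 * max(bc.total_flow, 1.0):
            raise ValueError(
                f"flow-assignment inconsistency at junction {node}: "
                f"inflow {avail:.6g} vs outlet demand {assigned:.6g}"
            )
        for e, q in demands:
            qe = rem if q is None else q
            if qe < -1e-9 * bc.total_flow:
                raise ValueError(f"negative flow on edge {e.name}: mass balance violated")
            flows[e.name] = qe
            inflow[e.node_v] += qe

    rows = []
    mu_pa_s = props.mu * 1e-3  # mPa s -> Pa s
    for e in tree.flow_edges():
        q = flows[e.name]                       # mm^3/s
        r, ln = e.radius, e.length              # mm
        v_mean = q / (math.pi * r**2)           # mm/s
        # dp = 8 mu L Q / (pi R^4): Pa s * mm^3/s / mm^3 = Pa * 1e-3... work in
        # SI-consistent mm units: mu[Pa s] * Q[mm^3/s] / mm^3 = Pa * (mm/mm) -> Pa
        dp = 8.0 * mu_pa_s * ln * q / (math.pi * r**4)      # Pa
        gamma = 4.0 * q / (math.pi * r**3)                   # 1/s
        tau = props.mu * gamma                               # mPa
        rows.append(
            dict(
                edge=e.name, group=e.group, node_u=e.node_u, node_v=e.node_v,
                radius_mm=r, length_mm=ln, Q_mm3_s=q, V_mean_mm_s=v_mean,
                V_max_mm_s=2.0 * v_mean, dp_Pa=dp, tau_mPa=tau, gamma_per_s=gamma,
            )
        )
    return pd.DataFrame(rows)
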