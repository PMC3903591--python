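"""Structured-text serialization: trees, boundary sets, Doppler tables.

Everything is plain text (JSON / CSV) with explicit units in the field names,
so outputs diff cleanly and round-trip exactly enough for downstream use.
Image stacks use TIFF via :mod:`fetalshear.imaging`; surfaces export through
:class:`fetalshear.surface.SurfaceMesh`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .boundaries import FlowBoundarySet
from .doppler import DopplerSet
from .stages import StageConfig
from .tree import FlowEdge, Junction, Landmark, TubeSegment, VesselTree


def _arr(a):
    return np.asarray(a).tolist()


def write_tree(tree: VesselTree, path: str | Path) -> None:
    d = {
        "config": {
            "age_days": tree.config.age_days,
            "heart_rate": tree.config.heart_rate,
            "ejection_ratio": tree.config.ejection_ratio,
            "term_day": tree.config.term_day,
            "dao_diameter": tree.config.dao_diameter,
            "seed": tree.config.seed,
        },
        "scale": tree.scale,
        "ductus_angle_deg": tree.ductus_angle_deg,
        "segments": [
            {
                "name": s.name, "role": s.role, "points": _arr(s.points),
                "radii": _arr(s.radii), "ellipticity": _arr(s.ellipticity),
                "elong_axis": _arr(s.elong_axis) if s.elong_axis is not None else None,
            }
            for s in tree.segments
        ],
        "junctions": [
            {"parent": j.parent, "child": j.child,
             "parent_arclength": j.parent_arclength, "point": _arr(j.point),
             "angle_deg": j.angle_deg}
            for j in tree.junctions
        ],
        "landmarks": {
            k: {"segment": v.segment, "arclength": v.arclength, "point": _arr(v.point)}
            for k, v in tree.landmarks.items()
        },
        "flow_edges": [
            {"name": e.name, "node_u": e.node_u, "node_v": e.node_v,
             "radius_mm": e.radius, "length_mm": e.length, "group": e.group}
            for e in tree.flow_edges()
        ],
        "inlet_nodes": tree.inlet_nodes,
        "outlet_nodes": tree.outlet_nodes,
        "provenance": tree.provenance,
    }
    Path(path).write_text(json.dumps(d))


def read_tree(path: str | Path) -> VesselTree:
    d = json.loads(Path(path).read_text())
    cfg = StageConfig(**d["config"])
    segs = [
        TubeSegment(
            name=s["name"], role=s["role"], points=np.array(s["points"]),
            radii=np.array(s["radii"]), ellipticity=np.array(s["ellipticity"]),
            elong_axis=np.array(s["elong_axis"]) if s["elong_axis"] is not None else None,
        )
        for s in d["segments"]
    ]
    juncs = [
        Junction(parent=j["parent"], child=j["child"],
                 parent_arclength=j["parent_arclength"], point=np.array(j["point"]),
                 angle_deg=j["angle_deg"])
        for j in d["junctions"]
    ]
    lms = {
        k: Landmark(segment=v["segment"], arclength=v["arclength"], point=np.array(v["point"]))
        for k, v in d["landmarks"].items()
    }
    edges = [
        FlowEdge(name=e["name"], node_u=e["node_u"], node_v=e["node_v"],
                 radius=e["radius_mm"], length=e["length_mm"], group=e["group"])
        for e in d["flow_edges"]
    ]
    return VesselTree(
        config=cfg, segments=segs, junctions=juncs, landmarks=lms,
        flow_edges_list=edges, inlet_nodes=d["inlet_nodes"],
        outlet_nodes=d["outlet_nodes"], ductus_angle_deg=d["ductus_angle_deg"],
        scale=d["scale"], provenance=d.get("provenance", {}),
    )


def write_boundary_set(bc: FlowBoundarySet, path: str | Path) -> None:
    d = {
        "age_days": bc.age_days,
        "dao_peak_velocity_mm_s": bc.dao_peak_velocity,
        "total_flow_mm3_s": bc.total_flow,
        "inlet_velocities_mm_s": bc.inlet_velocities,
        "inlet_radii_mm": bc.inlet_radii,
        "outlet_fractions": bc.outlet_fractions,
        "outlet_flows_mm3_s": bc.outlet_flows,
        "outlet_peak_velocities_mm_s": bc.outlet_peak_velocities,
    }
    Path(path).write_text(json.dumps(d, indent=1))


def write_doppler(doppler: DopplerSet, path: str | Path) -> None:
    doppler.records.to_csv(path, index=False)


def read_doppler_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
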