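"""Tube-fitted structured meshes and grid-independence bookkeeping.

Each vessel segment is meshed as a structured tube block (axial stations x
radial shells x azimuthal sectors).  Boundary extensions follow the simulation
protocol: every outlet is extended by 9 diameters so the outflow condition
cannot contaminate the region of interest, while the aortic and pulmonary
roots get only 1 diameter (they sit immediately downstream of the ventricles).
Two refinement levels of the same geometry support grid-independence checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tree import VesselTree

OUTLET_EXTENSION_DIAMETERS = 9.0
ROOT_EXTENSION_DIAMETERS = 1.0
REFINE_FACTOR = 2  # per-dimension cell multiplier per refinement level


@dataclass(frozen=True)
class TubeBlock:
    """One structured tube block of the mesh."""

    name: str
    kind: str                 # 'straight' | 'curved'
    radius: float             # mm
    length: float             # mm, including extensions
    bend_radius: float        # mm (inf for straight)
    nr: int
    nphi: int
    nz: int
    extension_in: float = 0.0   # mm
    extension_out: float = 0.0  # mm

    @property
    def cell_count(self) -> int:
        return (self.nr - 1) * self.nphi * (self.nz - 1)


@dataclass
class FlowMesh:
    """Named patches plus the tube blocks that realize them."""

    blocks: list[TubeBlock]
    patches: dict              # patch name -> 'inlet' | 'outlet' | 'wall'
    refinement: int = 0
    provenance: dict = field(default_factory=dict)

    @property
    def cell_count(self) -> int:
        return sum(b.cell_count for b in self.blocks)

    def patch_names(self, kind: str) -> list[str]:
        return [k for k, v in self.patches.items() if v == kind]


def _dims(radius: float, length: float, resolution: int) -> tuple[int, int, int]:
    f = REFINE_FACTOR**resolution
    nr = 9 * f + 1
    nphi = 16 * f
    nz = max(int(round(length / (radius / 4.0))) * f + 1, 9)
    return nr, nphi, nz


def mesh_tube(
    radius: float,
    length: float,
    resolution: int = 0,
    bend_radius: float = np.inf,
    name: str = "tube",
) -> FlowMesh:
    """Single-tube mesh with the canonical inlet/outlet/wall patches."""
    if radius <= 0 or length <= 0:
        raise ValueError("radius and length must be positive")
    nr, nphi, nz = _dims(radius, length, resolution)
    kind = "straight" if not np.isfinite(bend_radius) else "curved"
    blk = TubeBlock(
        name=name, kind=kind, radius=radius, length=length,
        bend_radius=bend_radius, nr=nr, nphi=nphi, nz=nz,
    )
    return FlowMesh(
        blocks=[blk],
        patches={"inlet": "inlet", "outlet": "outlet", "wall": "wall"},
        refinement=resolution,
    )


def mesh_tree(
    tree: VesselTree,
    resolution: int = 0,
    extensions: tuple[float, float] = (OUTLET_EXTENSION_DIAMETERS, ROOT_EXTENSION_DIAMETERS),
) -> FlowMesh:
    """Mesh every flow edge of a tree as a tube block, with extensions.

    Edges ending at an outlet node are lengthened by ``extensions[0]``
    diameters, edges starting at a root by ``extensions[1]`` diameters.  Patch
    names map to the tree's inlet/outlet nodes; all walls share one patch.
    """
    ext_out, ext_in = extensions
    blocks = []
    patches: dict[str, str] = {"wall": "wall"}
    for e in tree.flow_edges():
        add_in = ext_in * 2.0 * e.radius if e.node_u in tree.inlet_nodes else 0.0
        add_out = ext_out * 2.0 * e.radius if e.node_v in tree.outlet_nodes else 0.0
        length = e.length + add_in + add_out
        if length <= 0:
            raise ValueError(f"edge {e.name}: non-positive meshed length")
        nr, nphi, nz = _dims(e.radius, length, resolution)
        # curved blocks for the arch-like edges
        curved = e.name in ("isthmus", "ductus", "aao_root", "aao_mid1", "aao_mid2")
        bend = 4.0 * e.radius if curved else np.inf
        blocks.append(
            TubeBlock(
                name=e.name, kind="curved" if curved else "straight",
                radius=e.radius, length=length, bend_radius=bend,
                nr=nr, nphi=nphi, nz=nz,
                extension_in=add_in, extension_out=add_out,
            )
        )
        if e.node_u in tree.inlet_nodes:
            patches[f"inlet_{e.node_u}"] = "inlet"
        if e.node_v in tree.outlet_nodes:
            patches[f"outlet_{e.node_v}"] = "outlet"
    return FlowMesh(
        blocks=blocks, patches=patches, refinement=resolution,
        provenance={"extensions": extensions, "age_days": tree.config.age_days},
    )


def grid_independence(coarse, fine, metric) -> float:
    """Relative difference of a scalar metric between two refinement levels.

    ``coarse``/``fine`` may be any solution objects on the same geometry;
    ``metric`` is a callable evaluated on each.  Raises if the two solutions
    disagree on their geometry (radius/length attributes where present).
    """
    for attr in ("R", "L", "radius", "length"):
        a, b = getattr(coarse, attr, None), getattr(fine, attr, None)
        if a is not None and b is not None and abs(a - b) > 1e-9 * max(abs(a), 1.0):
            raise ValueError(f"mismatched geometry: {attr} differs ({a} vs {b})")
    mc, mf = float(metric(coarse)), float(metric(fine))
    denom = max(abs(mf), 1e-300)
    return abs(mf - mc) / denom
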