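"""Front door for 3D steady flow solutions on tube meshes.

Dispatches a single-block tube mesh to the appropriate solver: the
axisymmetric streamfunction-vorticity Navier-Stokes solver for straight tubes
(entrance development resolved), or the Dean perturbation solver for curved
tubes (fully developed secondary flow).  Either way the result is returned as
a :class:`~fetalshear.fields.FlowField` of 3D velocity/vorticity samples on
the structured tube grid.

For whole trees, ``solve_tree_fields`` solves each flow edge with its
reduced-order (Murray) flow split as the boundary condition — a segment-wise
composition that matches the reduced-order network by construction and is
validated against it; junction neighborhoods are not resolved.
"""

from __future__ import annotations

import numpy as np

from .blood import BloodProperties
from .boundaries import FlowBoundarySet
from .deanflow import CurvedTubeSolution, solve_curved_tube
from .fields import FlowField
from .meshing import FlowMesh, TubeBlock
from .network import solve_poiseuille_network
from .pipeflow import PipeFlowSolution, solve_pipe
from .tree import VesselTree


def pipe_solution_to_field(sol: PipeFlowSolution, nphi: int = 24) -> FlowField:
    """Revolve an axisymmetric solution into a 3D field along the z axis."""
    phis = np.linspace(0.0, 2.0 * np.pi, nphi, endpoint=False)
    nz, nr = sol.u_z.shape
    pts, vel, vort, wts, wall = [], [], [], [], []
    dz = sol.z[1] - sol.z[0]
    dr = sol.r[1] - sol.r[0]
    dphi = 2.0 * np.pi / nphi
    for i in range(nz):
        for j in range(nr):
            r = sol.r[j]
            for p in phis:
                c, s = np.cos(p), np.sin(p)
                pts.append([r * c, r * s, sol.z[i]])
                # radial + axial velocity; azimuthal vorticity
                vel.append([sol.u_r[i, j] * c, sol.u_r[i, j] * s, sol.u_z[i, j]])
                vort.append([-sol.omega[i, j] * s, sol.omega[i, j] * c, 0.0])
                wts.append(max(r, dr / 4.0) * dr * dphi * dz)
                wall.append(j == nr - 1)
    return FlowField(
        points=np.array(pts), velocity=np.array(vel), vorticity=np.array(vort),
        weights=np.array(wts), wall_mask=np.array(wall),
        meta=dict(kind="straight_tube", shape=(nz, nr, nphi), R=sol.R, L=sol.L,
                  v_mean=sol.v_mean, nu=sol.nu),
    )


def solve_steady_3d(
    mesh: FlowMesh,
    v_mean: float,
    props: BloodProperties | float,
    tol: float = 1e-6,
    inlet: str = "plug",
):
    """Steady laminar solution on a single-block tube mesh.

    Returns (solution, field): the native solution object (PipeFlowSolution or
    CurvedTubeSolution) and its 3D FlowField.  The configuration must be in
    the laminar steady regime (Re <= 100).
    """
    if len(mesh.blocks) != 1:
        raise ValueError(
            "solve_steady_3d operates on single-block meshes; "
            "use solve_tree_fields for a whole tree"
        )
    blk = mesh.blocks[0]
    nu = props.nu if hasattr(props, "nu") else float(props)
    re = 2.0 * v_mean * blk.radius / nu
    if re > 100.0:
        raise ValueError(f"Reynolds number {re:.1f} outside the laminar steady regime")
    if blk.kind == "straight":
        sol = solve_pipe(
            R=blk.radius, L=blk.length, v_mean=v_mean, props=nu,
            nr=blk.nr, nz=blk.nz, inlet=inlet, tol=tol,
        )
        return sol, pipe_solution_to_field(sol, nphi=blk.nphi)
    sol = solve_curved_tube(R=blk.radius, Rc=blk.bend_radius, v_mean=v_mean, props=nu)
    nzb = min(blk.nz, 24)
    field = sol.to_flow_field(
        arc_angle=blk.length / blk.bend_radius, nz=nzb, ns_out=blk.nr, nphi=blk.nphi
    )
    return sol, field


def solve_tree_fields(
    tree: VesselTree,
    bc: FlowBoundarySet,
    props: BloodProperties,
    mesh: FlowMesh | None = None,
    edges: list[str] | None = None,
) -> dict[str, tuple[object, FlowField]]:
    """Per-edge 3D fields with Murray-consistent flows (segment-wise).

    ``edges`` restricts the solve to named flow edges (default: all).  Flows
    come from the reduced-order network solution, so segment mass balance is
    exact by construction.
    """
    from .meshing import mesh_tree

    if mesh is None:
        mesh = mesh_tree(tree)
    net = solve_poiseuille_network(tree, bc, props)
    blocks = {b.name: b for b in mesh.blocks}
    out = {}
    for _, row in net.iterrows():
        if edges is not None and row["edge"] not in edges:
            continue
        blk: TubeBlock = blocks[row["edge"]]
        single = FlowMesh(blocks=[blk], patches={}, refinement=mesh.refinement)
        out[row["edge"]] = solve_steady_3d(single, row["V_mean_mm_s"], props)
    return out
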