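"""Lumen surface extraction and branch clipping.

``extract_surface`` triangulates the 0.5 iso-level of a segmented lumen in
physical (mm) coordinates.  The binary mask is first smoothed with a one-voxel
Gaussian so the iso-surface interpolates the staircase rather than tracing it
(sub-voxel accuracy for area and volume); tiny masks where smoothing would
erase the object fall back to the raw binary surface.

``clip_branches`` removes branch stubs at ostial planes and caps the resulting
holes, producing the trunk-only surface used for geometric analysis of the
aorta (all head-and-neck branches clipped, holes filled).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage
from skimage.measure import marching_cubes

from .segmentation import SegmentationMask


@dataclass(frozen=True)
class BranchClip:
    """Where and how to cut one branch off a trunk surface.

    ``point``: ostium position (mm); ``direction``: unit vector pointing from
    the trunk into the branch; ``radius``: branch radius (mm).
    """

    point: np.ndarray
    direction: np.ndarray
    radius: float


@dataclass
class SurfaceMesh:
    """Triangulated lumen surface in mm; thin wrapper around trimesh."""

    mesh: trimesh.Trimesh
    caps: int = 0                       # number of filled clip holes
    provenance: dict = field(default_factory=dict)

    @property
    def vertices(self) -> np.ndarray:
        return self.mesh.vertices

    @property
    def faces(self) -> np.ndarray:
        return self.mesh.faces

    @property
    def area(self) -> float:
        return float(self.mesh.area)

    @property
    def volume(self) -> float:
        return float(abs(self.mesh.volume))

    @property
    def is_watertight(self) -> bool:
        return bool(self.mesh.is_watertight)

    def export(self, path) -> None:
        """Write the surface (format from extension: .stl ascii, .obj, ...)."""
        from pathlib import Path

        path = Path(path)
        if path.suffix.lower() == ".stl":
            path.write_bytes(trimesh.exchange.stl.export_stl_ascii(self.mesh).encode())
        else:
            self.mesh.export(path)


def extract_surface(
    mask: SegmentationMask | np.ndarray,
    spacing_mm: np.ndarray | None = None,
    origin_mm: np.ndarray | None = None,
    smooth_sigma: float = 1.0,
) -> SurfaceMesh:
    """Triangulate the lumen boundary at the 0.5 iso-level, in mm.

    Raises on an empty mask.  The returned mesh is closed (watertight) and
    consistently oriented.
    """
    if isinstance(mask, SegmentationMask):
        vox = mask.voxels
        spacing_mm = mask.spacing_mm()
        origin_mm = mask.origin
    else:
        vox = np.asarray(mask, bool)
        spacing_mm = np.asarray(spacing_mm, float)
        origin_mm = np.zeros(3) if origin_mm is None else np.asarray(origin_mm, float)
    if vox.sum() == 0:
        raise ValueError("empty mask: no surface to extract")

    # pad so the surface always closes inside the grid
    pad = max(2, int(np.ceil(3 * smooth_sigma)))
    vol = np.pad(vox.astype(np.float64), pad)
    if smooth_sigma > 0:
        sm = ndimage.gaussian_filter(vol, smooth_sigma)
        if sm.max() < 0.6:   # object too thin for this smoothing scale
            sm = vol
    else:
        sm = vol
    verts, faces, _, _ = marching_cubes(sm, level=0.5, spacing=tuple(spacing_mm))
    # verts are in (z, y, x) axis order relative to the padded grid
    shift = pad * spacing_mm
    world = verts[:, ::-1] - shift[::-1] + origin_mm
    m = trimesh.Trimesh(vertices=world, faces=faces, process=True)
    trimesh.repair.fix_normals(m)
    return SurfaceMesh(mesh=m, provenance={"smooth_sigma": smooth_sigma})


def _cap_loops(vertices: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Fan-cap every open boundary loop; returns (vertices, faces, n_caps)."""
    m = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    edges = m.edges_sorted
    unique, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = unique[counts == 1]
    if len(boundary) == 0:
        return vertices, faces, 0
    # chain boundary edges into loops
    adj: dict[int, list[int]] = {}
    for a, b in boundary:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))
    seen = set()
    loops = []
    for start in adj:
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        prev, cur = None, start
        while True:
            nxts = [n for n in adj[cur] if n != prev]
            if not nxts:
                break
            nxt = nxts[0]
            if nxt == start:
                break
            if nxt in seen:
                break
            loop.append(nxt)
            seen.add(nxt)
            prev, cur = cur, nxt
        if len(loop) >= 3:
            loops.append(loop)
    v = vertices.copy()
    f = list(faces)
    for loop in loops:
        center = v[loop].mean(axis=0)
        ci = len(v)
        v = np.vstack([v, center[None, :]])
        for i in range(len(loop)):
            a, b = loop[i], loop[(i + 1) % len(loop)]
            f.append([a, b, ci])
    return v, np.array(f), len(loops)


def clip_branches(
    surface: SurfaceMesh,
    clips: list[BranchClip],
    offset_radii: float = 0.4,
    catch_radii: float = 2.2,
) -> SurfaceMesh:
    """Remove branch stubs at ostial planes and fill the holes with caps.

    For each clip, faces beyond the plane ``point + offset_radii*radius*
    direction`` (normal ``direction``) *and* within ``catch_radii*radius`` of
    the branch axis are deleted; each resulting boundary loop is capped with a
    triangle fan.  A clip whose ostium is not near the surface is rejected.
    Passing an empty clip list returns the surface unchanged.
    """
    if not clips:
        return surface
    m = surface.mesh
    keep = np.ones(len(m.faces), dtype=bool)
    for c in clips:
        p = np.asarray(c.point, float)
        d = np.asarray(c.direction, float)
        d = d / np.linalg.norm(d)
        near = np.linalg.norm(m.vertices - p, axis=1).min()
        if near > 2.0 * c.radius:
            raise ValueError(
                f"clip landmark {p} is {near:.3f} mm from the surface "
                f"(> {2 * c.radius:.3f} mm): not an ostium on this mesh"
            )
        cent = m.triangles_center
        rel = cent - p
        along = rel @ d
        radial = np.linalg.norm(rel - np.outer(along, d), axis=1)
        cut = (along > offset_radii * c.radius) & (radial < catch_radii * c.radius)
        keep &= ~cut
    if keep.all():
        return SurfaceMesh(mesh=m.copy(), caps=0, provenance=dict(surface.provenance))
    verts, faces, n_caps = _cap_loops(m.vertices, m.faces[keep])
    out = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    trimesh.repair.fix_normals(out)
    prov = dict(surface.provenance)
    prov["clipped"] = len(clips)
    return SurfaceMesh(mesh=out, caps=n_caps, provenance=prov)
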