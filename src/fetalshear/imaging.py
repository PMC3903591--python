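"""EFIC-like image stacks: voxelization of vessel trees and synthetic contrast.

Episcopic block-face imaging yields aligned 3D grayscale stacks in which the
blood volume (lumen) and surrounding tissue differ in mean intensity, with
speckle-like multiplicative noise.  The generator renders a parametric tube
tree into such a stack: lumen voxels around a lumen mean, tissue voxels around
a tissue mean, mean-one lognormal speckle of a configured coefficient of
variation.  The exact voxelized lumen mask is retained on the stack so every
downstream step (filtering, segmentation, morphometry) can be scored against
ground truth.

Conventions: axis order (slice, row, col) = (z, y, x) reversed into index
order (i0, i1, i2) -> (z, y, x); voxel centers at origin + index * spacing;
spacing in µm, world coordinates in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from . import geometry as geo
from .tree import TubeSegment, VesselTree

LUMEN_MEAN = 0.75
TISSUE_MEAN = 0.35
DEFAULT_SPACING_UM = 20.0
MAX_VOXELS = 80_000_000


@dataclass
class ImageStack:
    """3D grayscale stack with physical metadata and retained ground truth."""

    voxels: np.ndarray            # (nz, ny, nx) float32, axis order (slice,row,col)
    spacing: np.ndarray           # (3,) µm per axis, (slice,row,col)
    origin: np.ndarray            # (3,) mm, world position of voxel (0,0,0)
    provenance: dict = field(default_factory=dict)
    mask: np.ndarray | None = None  # ground-truth lumen mask, same shape

    def __post_init__(self) -> None:
        self.spacing = np.asarray(self.spacing, dtype=float)
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be strictly positive")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("stack intensities must be finite")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    def spacing_mm(self) -> np.ndarray:
        return self.spacing / 1000.0

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm()))


def _tube_samples(seg: TubeSegment, step_mm: float):
    """Resample a segment finely; return per-sample tube parameters."""
    n = max(4, int(np.ceil(seg.length / step_mm)) + 1)
    pts = geo.resample_polyline(seg.points, n)
    s_old = seg.arclength
    s_new = np.linspace(0.0, s_old[-1], n)
    radii = np.interp(s_new, s_old, seg.radii)
    ell = np.interp(s_new, s_old, seg.ellipticity)
    t, n1, n2 = geo.rotation_minimizing_frames(pts)
    if seg.elong_axis is not None:
        ax = np.empty((n, 3))
        for k in range(3):
            ax[:, k] = np.interp(s_new, s_old, seg.elong_axis[:, k])
    else:
        ax = np.zeros((n, 3))
    # major axis: projected elongation direction where present, else frame n1
    major = np.where(
        (np.linalg.norm(ax, axis=1) > 1e-6)[:, None],
        ax,
        n1,
    )
    major = major - np.einsum("ij,ij->i", major, t)[:, None] * t
    nrm = np.linalg.norm(major, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    major = major / nrm
    minor = np.cross(t, major)
    return pts, t, major, minor, radii, ell


def voxelize_tubes(
    segments: list[TubeSegment],
    spacing_um: float | tuple = DEFAULT_SPACING_UM,
    margin_mm: float = 0.08,
    max_voxels: int = MAX_VOXELS,
    bounds: tuple | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact voxel-center membership test against swept-ellipse tubes.

    Returns (mask, spacing_um[3], origin_mm[3]) with axis order (z, y, x).
    A voxel is lumen if its center lies inside any segment's local ellipse.
    """
    sp = np.broadcast_to(np.atleast_1d(np.asarray(spacing_um, float)), (3,)).copy()
    sp_mm = sp / 1000.0
    if bounds is None:
        lo = np.full(3, np.inf)
        hi = np.full(3, -np.inf)
        for s in segments:
            r = s.radii.max()
            lo = np.minimum(lo, s.points.min(axis=0) - r)
            hi = np.maximum(hi, s.points.max(axis=0) + r)
        lo -= margin_mm
        hi += margin_mm
    else:
        lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
        tree_lo, tree_hi = np.full(3, np.inf), np.full(3, -np.inf)
        for s in segments:
            tree_lo = np.minimum(tree_lo, s.points.min(axis=0) - s.radii.max())
            tree_hi = np.maximum(tree_hi, s.points.max(axis=0) + s.radii.max())
        if np.any(tree_lo < lo) or np.any(tree_hi > hi):
            raise ValueError("tree does not fit in the requested grid bounds")

    # grid axes: index order (z, y, x); world = origin + index * spacing
    n_xyz = np.maximum(np.ceil((hi - lo) / sp_mm[::-1]).astype(int) + 1, 2)
    nvox = int(np.prod(n_xyz))
    if nvox > max_voxels:
        raise ValueError(f"requested grid has {nvox} voxels (> {max_voxels})")
    origin = lo.copy()

    step = float(sp_mm.min()) * 0.5
    # each segment owns its membership test: a voxel is lumen if it falls
    # inside *any* segment's swept ellipse (pooling samples across segments
    # would let a nearby vessel's dense samples crowd out the right candidate)
    per_seg = []
    for seg in segments:
        p, t, ma, mi, r, e = _tube_samples(seg, step)
        per_seg.append(
            dict(P=p, T=t, MA=ma, MI=mi,
                 amaj=r / np.sqrt(e), amin=r * np.sqrt(e),
                 bound=r.max() / np.sqrt(e.min()) + 2 * step,
                 kdt=cKDTree(p), k=min(6, len(p)))
        )

    nx, ny, nz = n_xyz
    mask = np.zeros((nz, ny, nx), dtype=bool)
    xs = origin[0] + np.arange(nx) * sp_mm[2]
    ys = origin[1] + np.arange(ny) * sp_mm[1]
    zs = origin[2] + np.arange(nz) * sp_mm[0]

    chunk = max(1, int(2_000_000 // (ny * nx)) or 1)
    for z0 in range(0, nz, chunk):
        z1 = min(z0 + chunk, nz)
        Z, Y, X = np.meshgrid(zs[z0:z1], ys, xs, indexing="ij")
        vox = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        inside = np.zeros(len(vox), dtype=bool)
        for sg in per_seg:
            todo = ~inside
            if not todo.any():
                break
            dist, idx = sg["kdt"].query(
                vox[todo], k=sg["k"], distance_upper_bound=sg["bound"]
            )
            if sg["k"] == 1:
                dist = dist[:, None]; idx = idx[:, None]
            sub_inside = np.zeros(todo.sum(), dtype=bool)
            for kk in range(sg["k"]):
                valid = np.isfinite(dist[:, kk]) & ~sub_inside
                if not valid.any():
                    continue
                j = idx[valid, kk]
                d = vox[todo][valid] - sg["P"][j]
                dt = np.einsum("ij,ij->i", d, sg["T"][j])
                dmaj = np.einsum("ij,ij->i", d, sg["MA"][j])
                dmin = np.einsum("ij,ij->i", d, sg["MI"][j])
                ok = (np.abs(dt) <= 1.5 * step) & (
                    (dmaj / sg["amaj"][j]) ** 2 + (dmin / sg["amin"][j]) ** 2 <= 1.0
                )
                sub_inside[valid] = ok
            inside[todo] = sub_inside
        mask[z0:z1] = inside.reshape(z1 - z0, ny, nx)
    return mask, sp, origin


def rasterize_stack(
    tree: VesselTree | list[TubeSegment],
    spacing: float | tuple = DEFAULT_SPACING_UM,
    contrast: float = LUMEN_MEAN - TISSUE_MEAN,
    noise_sd: float = 0.15,
    seed: int = 0,
    tissue_mean: float = TISSUE_MEAN,
    bounds: tuple | None = None,
    max_voxels: int = MAX_VOXELS,
) -> ImageStack:
    """Render a vessel tree into an EFIC-like grayscale stack.

    ``noise_sd`` is the coefficient of variation of the mean-one lognormal
    speckle applied multiplicatively; 0 gives an exactly two-valued stack whose
    upper level coincides with the retained ground-truth mask.
    """
    segments = tree.segments if isinstance(tree, VesselTree) else list(tree)
    mask, sp, origin = voxelize_tubes(
        segments, spacing, bounds=bounds, max_voxels=max_voxels
    )
    lumen_mean = tissue_mean + contrast
    img = np.where(mask, lumen_mean, tissue_mean).astype(np.float64)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_sd**2))
        img *= rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=img.shape)
    prov = {
        "noise_sd": noise_sd,
        "seed": seed,
        "contrast": contrast,
        "tissue_mean": tissue_mean,
    }
    if isinstance(tree, VesselTree):
        prov["tree"] = dict(tree.provenance)
    return ImageStack(
        voxels=img.astype(np.float32), spacing=sp, origin=origin,
        provenance=prov, mask=mask,
    )


# ------------------------------------------------------------------ TIFF I/O

def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Multi-page TIFF (one page per slice) + JSON sidecar with metadata."""
    import json

    import tifffile

    path = Path(path)
    tifffile.imwrite(path, stack.voxels)
    meta = {
        "spacing_um": stack.spacing.tolist(),
        "origin_mm": stack.origin.tolist(),
        "axis_order": ["slice", "row", "col"],
        "provenance": stack.provenance,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    if stack.mask is not None:
        tifffile.imwrite(path.with_name(path.stem + "_mask" + path.suffix),
                         stack.mask.astype(np.uint8))


def read_stack(path: str | Path) -> ImageStack:
    import json

    import tifffile

    path = Path(path)
    vox = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    mask_path = path.with_name(path.stem + "_mask" + path.suffix)
    mask = tifffile.imread(mask_path).astype(bool) if mask_path.exists() else None
    return ImageStack(
        voxels=vox,
        spacing=np.array(meta["spacing_um"]),
        origin=np.array(meta["origin_mm"]),
        provenance=meta.get("provenance", {}),
        mask=mask,
    )
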