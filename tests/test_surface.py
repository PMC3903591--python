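"""Iso-surface extraction and branch clipping against analytic solids."""

import numpy as np
import pytest

from conftest import make_mask, straight_tube
from fetalshear.imaging import voxelize_tubes
from fetalshear.surface import BranchClip, clip_branches, extract_surface
from fetalshear.tree import TubeSegment


@pytest.fixture(scope="module")
def branched_tube():
    """Straight trunk (R=0.25, L=1) with one perpendicular branch (r=0.1)."""
    trunk = straight_tube(radius=0.25, length=1.0, n=50)
    bpts = np.column_stack([np.linspace(0, 0.5, 30), np.zeros(30), np.full(30, 0.5)])
    branch = TubeSegment("b", "innominate", bpts, np.full(30, 0.1), np.ones(30), None)
    mask, sp, orig = voxelize_tubes([trunk, branch], spacing_um=15.0)
    return extract_surface(mask, spacing_mm=sp / 1000.0, origin_mm=orig)


def test_sphere_area_and_volume():
    R, h = 0.3, 0.015  # spacing = R/20
    n = int(2 * (R + 0.1) / h)
    ax = (np.arange(n) - n / 2) * h
    Z, Y, X = np.meshgrid(ax, ax, ax, indexing="ij")
    mask = (X**2 + Y**2 + Z**2) <= R * R
    s = extract_surface(mask, spacing_mm=np.array([h, h, h]))
    assert s.is_watertight
    assert s.area == pytest.approx(4 * np.pi * R**2, rel=0.03)
    assert s.volume == pytest.approx(4 / 3 * np.pi * R**3, rel=0.02)


def test_cylinder_volume_and_voxel_agreement(cylinder_mask):
    s = extract_surface(cylinder_mask)
    vol_exact = np.pi * 0.25**2 * 1.2
    assert s.volume == pytest.approx(vol_exact, rel=0.02)
    assert s.volume == pytest.approx(cylinder_mask.volume_mm3(), rel=0.02)


def test_single_voxel_yields_closed_surface():
    m = np.zeros((5, 5, 5), bool)
    m[2, 2, 2] = True
    s = extract_surface(m, spacing_mm=np.array([0.01, 0.01, 0.01]))
    assert s.is_watertight
    assert s.volume > 0


def test_empty_mask_rejected():
    with pytest.raises(ValueError, match="empty"):
        extract_surface(np.zeros((4, 4, 4), bool), spacing_mm=np.array([0.01] * 3))


def test_clip_single_branch(branched_tube):
    clip = BranchClip(point=np.array([0.25, 0.0, 0.5]),
                      direction=np.array([1.0, 0.0, 0.0]), radius=0.1)
    out = clip_branches(branched_tube, [clip])
    assert out.caps == 1
    assert out.is_watertight
    # analytic trunk-with-cap area: closed cylinder + residual stub ring
    stub = 2 * np.pi * 0.1 * (0.4 * 0.1)
    analytic = 2 * np.pi * 0.25 * 1.0 + 2 * np.pi * 0.25**2 + stub
    assert out.area == pytest.approx(analytic, rel=0.05)


def test_clip_noop_and_bad_landmark(branched_tube):
    assert clip_branches(branched_tube, []).area == branched_tube.area
    far = BranchClip(point=np.array([5.0, 5.0, 5.0]),
                     direction=np.array([1.0, 0, 0]), radius=0.1)
    with pytest.raises(ValueError, match="not an ostium"):
        clip_branches(branched_tube, [far])


def test_clip_three_branches_creates_three_caps():
    trunk = straight_tube(radius=0.25, length=1.6, n=70)
    clips, segs = [], [trunk]
    for k, z in enumerate((0.4, 0.8, 1.2)):
        d = np.array([np.cos(k * 2.0), np.sin(k * 2.0), 0.0])
        bpts = np.column_stack([np.linspace(0, 0.45, 25) * d[0],
                                np.linspace(0, 0.45, 25) * d[1],
                                np.full(25, z)])
        bpts[:, :2] += 0.0
        segs.append(TubeSegment(f"b{k}", "innominate", bpts, np.full(25, 0.09),
                                np.ones(25), None))
        clips.append(BranchClip(point=0.25 * d + np.array([0, 0, z]),
                                direction=d, radius=0.09))
    mask, sp, orig = voxelize_tubes(segs, spacing_um=15.0)
    surf = extract_surface(mask, spacing_mm=sp / 1000.0, origin_mm=orig)
    out = clip_branches(surf, clips)
    assert out.caps == 3
    assert out.is_watertight
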