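"""Centerline extraction phantoms and insertion-angle geometry."""

import numpy as np
import pytest
from scipy.optimize import least_squares

from conftest import make_mask, straight_tube
from fetalshear.centerline import (
    Centerline,
    extract_centerline,
    find_bifurcation,
    insertion_angle,
)
from fetalshear.stages import make_stage_config, stage_sweep_ages
from fetalshear.tree import TubeSegment, ductus_angle_for_age, generate_vessel_tree


def test_straight_cylinder_centerline_on_axis(cylinder_mask):
    cl = extract_centerline(cylinder_mask, np.array([0, 0, 0.05]), np.array([0, 0, 1.15]))
    interior = (cl.points[:, 2] > 0.1) & (cl.points[:, 2] < 1.1)
    dev = np.linalg.norm(cl.points[interior][:, :2], axis=1).max()
    assert dev < 0.5 * 0.015  # half a voxel
    # inscribed-sphere radius near the true tube radius (EDT bias < 1.5 voxel)
    assert cl.a[interior].mean() == pytest.approx(0.25, abs=1.5 * 0.015)


def test_torus_bend_radius_recovered():
    Rb, rt = 0.8, 0.2
    th = np.linspace(0, np.pi * 0.75, 80)
    tpts = np.column_stack([Rb * np.cos(th), Rb * np.sin(th), np.zeros_like(th)])
    tseg = TubeSegment("torus", "arch", tpts, np.full(80, rt), np.ones(80), None)
    mask = make_mask([tseg], spacing_um=12.0)
    cl = extract_centerline(mask, tpts[2], tpts[-3])
    P = cl.points[5:-5, :2]

    def resid(p):
        return np.hypot(P[:, 0] - p[0], P[:, 1] - p[1]) - p[2]

    fit = least_squares(resid, x0=[P[:, 0].mean(), P[:, 1].mean(), 0.5])
    assert fit.x[2] == pytest.approx(Rb, rel=0.02)


def test_y_junction_single_bifurcation():
    trunk = straight_tube(radius=0.2, length=0.8, n=40)
    tips = []
    segs = [trunk]
    for sgn, nm in ((1.0, "l"), (-1.0, "r")):
        d = np.array([sgn * 0.5, 0, 0.8])
        d = d / np.linalg.norm(d)
        pts = np.array([0, 0, 0.8]) + np.linspace(0, 0.6, 30)[:, None] * d
        segs.append(TubeSegment(nm, "innominate", pts, np.full(30, 0.15),
                                np.ones(30), None))
        tips.append(pts[-2])
    mask = make_mask(segs, spacing_um=15.0)
    p1 = extract_centerline(mask, np.array([0, 0, 0.05]), tips[0])
    p2 = extract_centerline(mask, np.array([0, 0, 0.05]), tips[1])
    j = find_bifurcation(p1, p2, tol=0.06)
    # one split point, near the constructed junction (junction zone widening
    # pulls it slightly proximal)
    assert abs(j[2] - 0.8) < 0.25
    assert np.linalg.norm(j[:2]) < 0.1


def test_disconnected_lumen_rejected():
    a = straight_tube(radius=0.15, length=0.5, n=25)
    bpts = np.column_stack([np.full(25, 1.5), np.zeros(25), np.linspace(0, 0.5, 25)])
    b = TubeSegment("far", "innominate", bpts, np.full(25, 0.15), np.ones(25), None)
    mask = make_mask([a, b], spacing_um=20.0)
    with pytest.raises(ValueError, match="disconnected"):
        extract_centerline(mask, np.array([0, 0, 0.25]), np.array([1.5, 0, 0.25]))


def test_ground_truth_radius_definition():
    """a = average of max and min section radii of the swept ellipse."""
    seg = straight_tube(radius=0.2, ellipticity=0.64, elong=[1, 0, 0])
    cl = Centerline.from_segment(seg)
    expected = 0.5 * 0.2 * (1 / 0.8 + 0.8)
    assert np.allclose(cl.a, expected)


def _line_cl(p0, d, n=30, a=0.1):
    d = np.asarray(d, float) / np.linalg.norm(d)
    pts = np.asarray(p0, float) + np.linspace(0, 1.0, n)[:, None] * d
    t = np.tile(d, (n, 1))
    s = np.linspace(0, 1.0, n)
    return Centerline(points=pts, tangents=t, arclength=s, a=np.full(n, a))


def test_insertion_angle_perpendicular_and_parallel():
    parent = _line_cl([0, 0, 1.0], [0, 0, -1])         # flows downward
    junction = np.array([0, 0, 0.5])
    perp = _line_cl([-1.0, 0, 0.5], [1, 0, 0])         # arrives sideways
    assert insertion_angle(parent, perp, junction) == pytest.approx(90.0, abs=2.0)
    par = _line_cl([0, 0, 1.5], [0, 0, -1])            # arrives parallel
    assert insertion_angle(parent, par, junction) == pytest.approx(180.0, abs=2.0)


def test_insertion_angle_junction_mismatch_rejected():
    parent = _line_cl([0, 0, 1.0], [0, 0, -1])
    branch = _line_cl([-1.0, 0, 0.5], [1, 0, 0])
    with pytest.raises(ValueError, match="junction mismatch"):
        insertion_angle(parent, branch, np.array([5.0, 5.0, 5.0]), tol=0.1)


def test_ductus_angle_trend_recovered_within_five_degrees():
    recovered = []
    for i, t in enumerate(stage_sweep_ages()):
        tree = generate_vessel_tree(make_stage_config(t, seed=21 + i))
        parent = Centerline.from_segment(tree.get("descending_aorta"))
        branch = Centerline.from_segment(tree.get("ductus"))
        ang = insertion_angle(parent, branch, tree.landmarks["ductus_insertion"].point)
        assert ang == pytest.approx(ductus_angle_for_age(t), abs=5.0)
        recovered.append(ang)
    assert all(a < b for a, b in zip(recovered, recovered[1:]))
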