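"""Cross-section morphometry and landmark-aligned profiles."""

import numpy as np
import pytest

from conftest import make_mask, straight_tube
from fetalshear.centerline import Centerline
from fetalshear.sections import SubjectProfile, align_profiles, section_metrics
from fetalshear.tree import TubeSegment


def test_circular_tube_sections(cylinder_mask):
    seg = straight_tube()
    cl = Centerline.from_segment(seg)
    secs = section_metrics(cl, cylinder_mask, stations=np.linspace(0.2, 1.0, 7))
    areas = np.array([s.area for s in secs])
    aspects = np.array([s.aspect_ratio for s in secs])
    assert np.allclose(areas, np.pi * 0.25**2, rtol=0.02)
    assert np.all(aspects > 0.97)


def test_elliptical_tube_aspect_ratio_within_two_percent():
    e = 0.7
    seg = straight_tube(ellipticity=e, elong=[1, 0, 0])
    mask = make_mask([seg], spacing_um=12.0)
    cl = Centerline.from_segment(seg)
    secs = section_metrics(cl, mask, stations=np.linspace(0.2, 1.0, 9))
    aspect = np.mean([s.aspect_ratio for s in secs])
    assert aspect == pytest.approx(e, rel=0.02)
    # elongation along the imposed major axis
    for s in secs:
        cosang = abs(np.dot(s.elongation_axis, [1, 0, 0]))
        assert np.degrees(np.arccos(np.clip(cosang, 0, 1))) < 15.0


def test_aspect_ratio_rotation_invariant():
    e = 0.7
    ang = np.deg2rad(30)
    c, s_ = np.cos(ang), np.sin(ang)
    Rm = np.array([[1, 0, 0], [0, c, -s_], [0, s_, c]])
    base = straight_tube(ellipticity=e, elong=[1, 0, 0])
    rot = TubeSegment("r", base.role, base.points @ Rm.T, base.radii,
                      base.ellipticity, base.elong_axis)
    vals = []
    for seg in (base, rot):
        mask = make_mask([seg], spacing_um=12.0)
        cl = Centerline.from_segment(seg)
        secs = section_metrics(cl, mask, stations=np.linspace(0.2, 1.0, 7))
        vals.append(np.mean([s.aspect_ratio for s in secs]))
    assert vals[1] == pytest.approx(vals[0], rel=0.03)


def test_branch_zone_ellipticity_recovered():
    """Imposed 0.7 dip at the ostium recovered within +-0.05, elongation
    toward the branch within 15 degrees (measured proximal to the open mouth).
    """
    n = 60
    pts = np.column_stack([np.zeros(n), np.zeros(n), np.linspace(0, 1.2, n)])
    s_arr = np.linspace(0, 1.2, n)
    bdir = np.array([1.0, 0.0, 0.0])
    dip = 0.9 - 0.2 * np.exp(-0.5 * ((s_arr - 0.6) / 0.1) ** 2)
    parent = TubeSegment("p", "ascending_aorta", pts, np.full(n, 0.25), dip,
                         np.tile(bdir, (n, 1)))
    bpts = np.column_stack([np.linspace(0, 0.5, 25), np.zeros(25), np.full(25, 0.6)])
    branch = TubeSegment("b", "innominate", bpts, np.full(25, 0.1), np.ones(25), None)
    mask = make_mask([parent, branch], spacing_um=12.0)
    cl = Centerline.from_segment(parent)
    # proximal to the ostium, outside the open mouth (|s - 0.6| > 1.2 r_branch)
    stations = np.linspace(0.30, 0.47, 6)
    secs = section_metrics(cl, mask, stations=stations)
    min_aspect = min(s.aspect_ratio for s in secs)
    imposed_min = dip[np.argmin(abs(s_arr - 0.47))]
    assert min_aspect == pytest.approx(imposed_min, abs=0.05)
    worst = min(secs, key=lambda s: s.aspect_ratio)
    cosang = abs(np.dot(worst.elongation_axis, bdir))
    assert np.degrees(np.arccos(np.clip(cosang, 0, 1))) < 15.0


def test_station_out_of_range_rejected(cylinder_mask):
    cl = Centerline.from_segment(straight_tube())
    with pytest.raises(ValueError, match="stations"):
        section_metrics(cl, cylinder_mask, stations=np.array([5.0]))


def test_section_plane_exiting_grid_is_flagged():
    seg = straight_tube(radius=0.25, length=0.4, n=20)
    mask = make_mask([seg], spacing_um=25.0)
    cl = Centerline.from_segment(seg)
    secs = section_metrics(cl, mask, stations=np.array([0.2]), extent_factor=12.0)
    assert secs[0].flagged


# ----------------------------------------------------------- align_profiles

def _prof(landmarks, sid, length=10.0, values=None, n=50):
    x = np.linspace(0, length, n)
    v = values if values is not None else np.ones(n)
    return SubjectProfile(x=x, values=np.asarray(v, float) * np.ones(n),
                          landmarks={k: p * length for k, p in landmarks.items()},
                          subject_id=sid)


def test_single_subject_alignment_is_identity():
    p = _prof({"a": 0.2, "b": 0.5}, "s1")
    out = align_profiles([p], ["a", "b"])
    assert out.landmarks["a"] == pytest.approx(0.2)
    assert out.landmarks["b"] == pytest.approx(0.5)


def test_two_subject_landmarks_pinned_to_mean():
    p1 = _prof({"a": 0.2, "b": 0.5}, "s1")
    p2 = _prof({"a": 0.3, "b": 0.6}, "s2")
    out = align_profiles([p1, p2], ["a", "b"])
    assert out.landmarks["a"] == pytest.approx(0.25)
    assert out.landmarks["b"] == pytest.approx(0.55)


def test_constant_profiles_average_exactly():
    ps = [_prof({"a": 0.2 + 0.05 * i}, f"s{i}", values=3.7) for i in range(3)]
    out = align_profiles(ps, ["a"])
    assert np.allclose(out.mean, 3.7)
    assert np.allclose(out.sd, 0.0)


def test_alignment_rejects_missing_or_disordered_landmarks():
    good = _prof({"a": 0.2, "b": 0.5}, "s1")
    missing = _prof({"a": 0.2}, "s2")
    with pytest.raises(ValueError, match="missing"):
        align_profiles([good, missing], ["a", "b"])
    disordered = _prof({"a": 0.5, "b": 0.2}, "s3")
    with pytest.raises(ValueError, match="out of order"):
        align_profiles([good, disordered], ["a", "b"])
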