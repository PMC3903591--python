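"""Synthetic great-artery trees: determinism, anchors, growth, Murray radii."""

import numpy as np
import pytest

from fetalshear.stages import make_stage_config, stage_sweep_ages
from fetalshear.tree import (
    GeometryError,
    TubeSegment,
    VesselTree,
    ductus_angle_for_age,
    generate_vessel_tree,
    _check_overlaps,
)


def test_same_seed_bitwise_identical():
    a = generate_vessel_tree(make_stage_config(16.5, seed=42))
    b = generate_vessel_tree(make_stage_config(16.5, seed=42))
    for sa, sb in zip(a.segments, b.segments):
        assert np.array_equal(sa.points, sb.points)
        assert np.array_equal(sa.radii, sb.radii)
        assert np.array_equal(sa.ellipticity, sb.ellipticity)


def test_dao_width_anchor(tree_e185):
    """Near term the DAo max cross-section width equals the 0.573 mm anchor."""
    dao = tree_e185.get("descending_aorta")
    width = 2.0 * dao.radii.max() / np.sqrt(dao.ellipticity.min())
    assert width == pytest.approx(0.573, rel=1e-9)


def test_mean_area_strictly_increases_with_age():
    areas = []
    for i, t in enumerate(stage_sweep_ages()):
        tree = generate_vessel_tree(make_stage_config(t, seed=5 + i))
        areas.append(tree.get("descending_aorta").mean_area())
    assert all(a1 < a2 for a1, a2 in zip(areas, areas[1:]))


def test_ductus_angle_opens_toward_parallel():
    angles = [
        generate_vessel_tree(make_stage_config(t, seed=1)).ductus_angle_deg
        for t in stage_sweep_ages()
    ]
    assert all(a1 < a2 for a1, a2 in zip(angles, angles[1:]))
    assert angles[0] == pytest.approx(ductus_angle_for_age(14.5))
    assert angles[-1] <= 180.0


def test_murray_consistent_internal_radii(tree_e185):
    """Every internal flow-edge radius is the cube-root of downstream cubes."""
    edges = {e.name: e for e in tree_e185.flow_edges()}
    out = tree_e185.outlet_radii()
    r_in = edges["innominate"].radius
    r_lcc = edges["left_common_carotid"].radius
    r_lsc = edges["left_subclavian"].radius
    assert edges["aao_mid1"].radius ** 3 == pytest.approx(
        edges["aao_root"].radius ** 3 - r_in**3
    )
    assert edges["isthmus"].radius ** 3 == pytest.approx(
        edges["aao_mid2"].radius ** 3 - r_lsc**3
    )
    # both roots equal, and the whole tree closes: roots' cubes = outlet cubes
    assert edges["aao_root"].radius == pytest.approx(edges["pulmonary_trunk"].radius)
    assert 2 * edges["aao_root"].radius ** 3 == pytest.approx(
        sum(r**3 for r in out.values())
    )


def test_branch_zone_ellipticity_dips_toward_branch(tree_e185):
    asc = tree_e185.get("ascending_aorta")
    assert asc.ellipticity.min() == pytest.approx(0.7, abs=1e-6)
    assert np.all(asc.ellipticity <= 1.0)
    # elongation at the deepest dip points along the branch direction
    i = int(np.argmin(asc.ellipticity))
    ax = asc.elong_axis[i]
    assert np.linalg.norm(ax) == pytest.approx(1.0, abs=1e-6)


def test_nonphysical_segment_rejected():
    pts = np.column_stack([np.zeros(9), np.zeros(9), np.linspace(0, 1, 9)])
    with pytest.raises(GeometryError):
        TubeSegment("x", "ductus", pts, np.full(9, -0.1), np.ones(9), None)
    with pytest.raises(GeometryError):
        TubeSegment("x", "ductus", pts, np.full(9, 0.1), np.full(9, 1.5), None)


def test_overlapping_vessels_rejected(tree_e185):
    pts = np.column_stack([np.zeros(20), np.zeros(20), np.linspace(0, 1, 20)])
    a = TubeSegment("a", "innominate", pts, np.full(20, 0.2), np.ones(20), None)
    b = TubeSegment(
        "b", "left_common_carotid", pts + np.array([0.05, 0, 0]),
        np.full(20, 0.2), np.ones(20), None,
    )
    fake = VesselTree(
        config=tree_e185.config, segments=[a, b], junctions=[], landmarks={},
        flow_edges_list=[], inlet_nodes={}, outlet_nodes={},
        ductus_angle_deg=120.0, scale=1.0,
    )
    with pytest.raises(GeometryError, match="overlap"):
        _check_overlaps(fake)
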