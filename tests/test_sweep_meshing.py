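"""End-to-end stage sweep, meshing bookkeeping, grid independence."""

import numpy as np
import pandas as pd
import pytest

from fetalshear.meshing import FlowMesh, grid_independence, mesh_tree, mesh_tube
from fetalshear.pipeflow import solve_pipe
from fetalshear.solver3d import solve_steady_3d
from fetalshear.sweep import run_stage_sweep


def test_sweep_deterministic():
    a = run_stage_sweep(seed=5)
    b = run_stage_sweep(seed=5)
    pd.testing.assert_frame_equal(a.trend_table, b.trend_table)
    pd.testing.assert_frame_equal(a.murray_validation, b.murray_validation)


def test_shear_constancy_while_vessels_grow(sweep_default):
    assert sweep_default.tau_relative_spread() < 0.10
    assert sweep_default.area_growth_factor() > 2.0


def test_velocity_and_area_trends_strongly_positive(sweep_default):
    st = sweep_default.trend_stats.set_index(["quantity", "covariate"])
    assert st.loc[("V_c_mm_s", "age_days"), "rho"] > 0.6
    assert st.loc[("area_mm2", "age_days"), "rho"] > 0.6
    # shear stress statistically independent of vessel size: the zero-slope
    # hypothesis is not rejected
    assert st.loc[("tau_mPa", "area_mm2"), "p_zero_slope"] > 0.05


def test_murray_validation_passes_at_every_age(sweep_default):
    assert (sweep_default.murray_validation.p_value > 0.1).all()


def test_straight_tube_mesh_has_three_patches():
    m = mesh_tube(radius=0.25, length=1.0)
    assert sorted(m.patches.values()) == ["inlet", "outlet", "wall"]


def test_refinement_multiplies_cell_count():
    m0 = mesh_tube(radius=0.25, length=1.0, resolution=0)
    m1 = mesh_tube(radius=0.25, length=1.0, resolution=1)
    assert m1.cell_count == pytest.approx(8 * m0.cell_count, rel=0.15)


def test_tree_mesh_patch_bookkeeping(tree_e185):
    m = mesh_tree(tree_e185)
    assert len(m.patch_names("outlet")) == len(tree_e185.outlet_nodes)
    assert len(m.patch_names("inlet")) == len(tree_e185.inlet_nodes)
    # outlet extensions are 9 diameters, root extensions 1 diameter
    blocks = {b.name: b for b in m.blocks}
    dao = blocks["dao"]
    assert dao.extension_out == pytest.approx(9 * 2 * dao.radius)
    root = blocks["aao_root"]
    assert root.extension_in == pytest.approx(1 * 2 * root.radius)


def test_grid_independence_identity_and_mismatch(pipe_fine):
    assert grid_independence(pipe_fine, pipe_fine, lambda s: s.wall_shear_rate()[-1]) == 0.0
    other = solve_pipe(R=0.15, L=1.0, v_mean=10.0, props=2.5, nr=9, nz=21)
    with pytest.raises(ValueError, match="mismatched"):
        grid_independence(pipe_fine, other, lambda s: s.v_mean)


def test_grid_independence_decreases_with_refinement():
    coarse = solve_pipe(R=0.29, L=2.9, v_mean=65.0, props=2.5, nr=9, nz=31)
    mid = solve_pipe(R=0.29, L=2.9, v_mean=65.0, props=2.5, nr=17, nz=61)
    fine = solve_pipe(R=0.29, L=2.9, v_mean=65.0, props=2.5, nr=33, nz=121)
    d1 = grid_independence(coarse, mid, lambda s: s.wall_shear_rate()[-1])
    d2 = grid_independence(mid, fine, lambda s: s.wall_shear_rate()[-1])
    assert d2 < d1
    assert d2 < 0.05  # the refinement-acceptance gate


def test_solve_steady_3d_dispatch():
    m = mesh_tube(radius=0.2, length=1.0)
    sol, field = solve_steady_3d(m, v_mean=20.0, props=2.5)
    assert field.meta["kind"] == "straight_tube"
    assert abs(field.velocity[:, 2]).max() > 0
    mc = mesh_tube(radius=0.2, length=0.8, bend_radius=0.8)
    solc, fieldc = solve_steady_3d(mc, v_mean=20.0, props=2.5)
    assert fieldc.meta["kind"] == "curved_tube"
    with pytest.raises(ValueError, match="laminar"):
        solve_steady_3d(m, v_mean=5000.0, props=2.5)
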