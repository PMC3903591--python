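"""Dean secondary flow: closed-form oracle, symmetry, helicity, mixing."""

import numpy as np
import pytest

from fetalshear.deanflow import (
    dean_number,
    solve_curved_tube,
    solve_dean_mode,
    trace_mixing,
)
from fetalshear.hemodynamics import normalized_helicity
from fetalshear.pipeflow import solve_pipe
from fetalshear.solver3d import pipe_solution_to_field


def dean_series(s, C):
    """Dean's closed-form solution of L1 L1 f = C s (1 - s^2), clamped rim."""
    return C * (s / 288.0 - s**3 / 128.0 + s**5 / 192.0 - s**7 / 1152.0)


def test_numeric_mode_matches_closed_form():
    s, f, _ = solve_dean_mode(201, C=3.7)
    exact = dean_series(s, 3.7)
    assert np.abs(f - exact).max() <= 1e-3 * np.abs(exact).max()


@pytest.fixture(scope="module")
def arch_solution():
    return solve_curved_tube(R=0.21, Rc=0.5, v_mean=50.0, props=2.3)


def test_two_counter_rotating_cells(arch_solution):
    """f single-signed => exactly one cell per half-plane, opposite rotation."""
    f = arch_solution.f
    interior = f[3:-3]
    assert np.all(interior > 0) or np.all(interior < 0)
    cs = arch_solution.cross_section_field()
    # secondary velocity antisymmetric across the curvature plane (y -> -y):
    # u_x even, u_y odd
    ux_p, uy_p = arch_solution.secondary_velocity(np.full(8, 0.5),
                                                  np.linspace(0.2, 2.9, 8))
    ux_m, uy_m = arch_solution.secondary_velocity(np.full(8, 0.5),
                                                  -np.linspace(0.2, 2.9, 8))
    assert np.allclose(ux_p, ux_m, atol=1e-12)
    assert np.allclose(uy_p, -uy_m, atol=1e-12)


def test_cross_plane_kinetic_energy_mirror_symmetric(arch_solution):
    cs = arch_solution.cross_section_field(ns_out=30, nphi=64)
    ke = cs["u_x"] ** 2 + cs["u_y"] ** 2
    y = np.sin(cs["phi"])[None, :] * cs["s"][:, None]
    upper, lower = ke[:, np.sin(cs["phi"]) > 0].sum(), ke[:, np.sin(cs["phi"]) < 0].sum()
    assert abs(upper - lower) / max(upper, lower) < 0.05


def test_helicity_bounded_and_chirality_balanced(arch_solution):
    field = arch_solution.to_flow_field(arc_angle=np.pi / 2)
    hel = normalized_helicity(field)
    assert np.all(np.abs(hel.hn) <= 1.0)
    assert hel.chirality_imbalance() < 0.10


def test_straight_tube_helicity_negligible():
    sol = solve_pipe(R=0.25, L=1.0, v_mean=30.0, props=2.3, nr=17, nz=41)
    field = pipe_solution_to_field(sol, nphi=16)
    hel = normalized_helicity(field)
    assert np.abs(hel.hn).max() < 0.02


def test_tracer_streams_do_not_mix(arch_solution):
    mix = trace_mixing(arch_solution, length=2.0, n_particles=300, seed=3)
    assert mix < 0.05


def test_dean_number_scaling():
    assert dean_number(0.2, 0.8, 50.0, 2.5) == pytest.approx(
        2 * 50 * 0.2 / 2.5 * np.sqrt(0.25)
    )


def test_invalid_geometry_rejected():
    with pytest.raises(ValueError):
        solve_curved_tube(R=0.5, Rc=0.4, v_mean=10, props=2.5)
    with pytest.raises(ValueError):
        solve_dean_mode(4)
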