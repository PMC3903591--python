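"""Wall shear fields, unwrapped maps, and centerline dimensionless numbers."""

import numpy as np
import pytest

from fetalshear.blood import blood_at_age, viscosity_from_hct
from fetalshear.boundaries import assemble_boundaries
from fetalshear.centerline import Centerline
from fetalshear.hemodynamics import centerline_hemodynamics, reynolds, womersley
from fetalshear.network import solve_poiseuille_network
from fetalshear.pipeflow import PipeFlowSolution, solve_pipe
from fetalshear.stages import make_stage_config
from fetalshear.velocity import VelocityAgeModel, default_velocity_coeffs
from fetalshear.wallshear import unwrap_map, wall_shear

PROPS = viscosity_from_hct(0.40)


@pytest.fixture(scope="module")
def pipe_small():
    return solve_pipe(R=0.25, L=1.5, v_mean=40.0, props=PROPS.nu, nr=25, nz=81)


def test_tau_is_mu_times_gamma_everywhere(pipe_small):
    wsf = wall_shear(pipe_small, PROPS)
    assert np.allclose(wsf.samples.tau_mPa, PROPS.mu * wsf.samples.gamma_per_s,
                       rtol=1e-6)


def test_poiseuille_tube_mean_tau(pipe_small):
    """Area-mean tau matches 4 mu Q / (pi R^3) within 3% past the entrance."""
    wsf = wall_shear(pipe_small, PROPS)
    s = wsf.samples
    developed = s[s.arclength_mm > 0.75]
    tau_exact = 4 * PROPS.mu * 40.0 / 0.25  # 4 mu v_mean / R, mPa
    assert developed.tau_mPa.mean() == pytest.approx(tau_exact, rel=0.03)


def test_zero_field_gives_zero_shear():
    nz, nr = 11, 9
    sol = PipeFlowSolution(
        R=0.2, L=1.0, r=np.linspace(0, 0.2, nr), z=np.linspace(0, 1, nz),
        u_z=np.zeros((nz, nr)), u_r=np.zeros((nz, nr)),
        psi=np.zeros((nz, nr)), omega=np.zeros((nz, nr)),
        v_mean=1.0, nu=2.5,
    )
    wsf = wall_shear(sol, PROPS)
    assert np.allclose(wsf.samples.tau_mPa, 0.0)
    assert np.allclose(wsf.samples.gamma_per_s, 0.0)


def test_uniform_shear_gives_constant_map(pipe_small):
    wsf = wall_shear(pipe_small, PROPS)
    developed = wsf.samples[wsf.samples.arclength_mm > 0.75]
    from fetalshear.wallshear import WallShearField

    umap = unwrap_map(WallShearField(samples=developed, mu=PROPS.mu))
    vals = umap.values[np.isfinite(umap.values)]
    assert (vals.max() - vals.min()) < 0.02 * vals.mean()
    assert umap.masked_mean() == pytest.approx(developed.tau_mPa.mean(), rel=0.01)


def test_single_branch_hole_bookkeeping(pipe_small):
    wsf = wall_shear(pipe_small, PROPS)
    umap = unwrap_map(wsf, holes=[(0.7, 90.0, 0.08)])
    assert umap.holes == 1
    assert np.all(np.isnan(umap.values[umap.hole_mask]))
    # a hole straddling the azimuth origin still counts once
    umap2 = unwrap_map(wsf, holes=[(0.7, 0.0, 0.08)])
    assert umap2.holes == 1


def test_reynolds_and_womersley_arithmetic():
    assert reynolds(10.0, 0.25, 2.5) == pytest.approx(1.0)
    assert reynolds(0.0, 0.25, 2.5) == 0.0
    assert womersley(0.25, 25.0, 2.5) == pytest.approx(0.25 * np.sqrt(10.0))


def test_centerline_hemodynamics_table():
    n = 20
    pts = np.column_stack([np.zeros(n), np.zeros(n), np.linspace(0, 1, n)])
    cl = Centerline(points=pts, tangents=np.tile([0, 0, 1.0], (n, 1)),
                    arclength=np.linspace(0, 1, n), a=np.full(n, 0.25))
    cfg = make_stage_config(18.5)
    hemo = centerline_hemodynamics(10.0, cl, PROPS, cfg)
    assert hemo.table.Re.iloc[0] == pytest.approx(10.0 * 0.25 / PROPS.nu)
    assert np.allclose(hemo.table.alpha, 0.25 * np.sqrt(cfg.omega / PROPS.nu))
    with pytest.raises(ValueError):
        centerline_hemodynamics(-5.0, cl, PROPS, cfg)


def test_stage_sweep_reynolds_below_thirty(sweep_default):
    """Centerline-averaged peak-flow Re < 30 for every vessel and stage."""
    assert (sweep_default.trend_table.Re < 30).all()


def test_network_wall_shear_field(tree_e185):
    props = blood_at_age(18.5)
    model = VelocityAgeModel(coeffs=default_velocity_coeffs())
    bc = assemble_boundaries(tree_e185, model)
    net = solve_poiseuille_network(tree_e185, bc, props)
    wsf = wall_shear(net, props)
    assert set(wsf.samples.segment) == set(net.edge)
    assert np.allclose(wsf.samples.tau_mPa, props.mu * wsf.samples.gamma_per_s)
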