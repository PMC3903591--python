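"""Murray's-law flow splits, boundary assembly, and the Poiseuille network."""

import dataclasses
import math

import numpy as np
import pytest

from fetalshear.blood import blood_at_age
from fetalshear.boundaries import assemble_boundaries, murray_fractions
from fetalshear.network import solve_poiseuille_network
from fetalshear.velocity import VelocityAgeModel, default_velocity_coeffs

MODEL = VelocityAgeModel(coeffs=default_velocity_coeffs())


@pytest.mark.parametrize(
    "radii, expected",
    [
        ([1.0, 1.0], [0.5, 0.5]),
        ([2.0, 1.0], [8 / 9, 1 / 9]),
        ([1.0, 1.0, 1.0, 1.0], [0.25] * 4),
    ],
)
def test_murray_fraction_examples(radii, expected):
    assert np.allclose(murray_fractions(radii), expected)


def test_murray_fraction_errors():
    with pytest.raises(ValueError, match="empty"):
        murray_fractions([])
    with pytest.raises(ValueError, match="positive"):
        murray_fractions([1.0, -0.5])


def test_murray_scale_invariance():
    r = np.array([0.3, 0.12, 0.09])
    assert np.allclose(murray_fractions(r), murray_fractions(10.0 * r))


def test_dao_flow_is_half_peak_times_area(tree_e185):
    bc = assemble_boundaries(tree_e185, MODEL)
    r = tree_e185.dao_radius
    v = MODEL(18.5)
    assert bc.outlet_flows["out_descending_aorta"] == pytest.approx(
        v * math.pi * r**2 / 2.0
    )


def test_inflow_balances_outflow_exactly(tree_e185):
    bc = assemble_boundaries(tree_e185, MODEL)
    assert abs(bc.inlet_flow() - bc.outlet_flow()) <= 1e-9 * bc.total_flow
    assert sum(bc.outlet_fractions.values()) == pytest.approx(1.0, abs=1e-12)
    assert all(0 < f < 1 for f in bc.outlet_fractions.values())
    # both roots get the same plug velocity
    vals = list(bc.inlet_velocities.values())
    assert vals[0] == pytest.approx(vals[1])


def test_network_poiseuille_relations(tree_e185):
    props = blood_at_age(18.5)
    bc = assemble_boundaries(tree_e185, MODEL)
    df = solve_poiseuille_network(tree_e185, bc, props)
    # definitional relations hold on every edge
    q = df.Q_mm3_s.to_numpy()
    r = df.radius_mm.to_numpy()
    assert np.allclose(df.gamma_per_s, 4 * q / (np.pi * r**3))
    assert np.allclose(df.tau_mPa, props.mu * df.gamma_per_s)
    assert np.allclose(df.V_max_mm_s, 2 * q / (np.pi * r**2))
    # single-tube spot value: tau = 4 mu Q / (pi R^3)
    row = df[df.edge == "dao"].iloc[0]
    assert row.tau_mPa == pytest.approx(
        4 * props.mu * row.Q_mm3_s / (np.pi * row.radius_mm**3), rel=1e-12
    )


def test_symmetric_branches_get_equal_flow(tree_e185):
    props = blood_at_age(18.5)
    bc = assemble_boundaries(tree_e185, MODEL)
    df = solve_poiseuille_network(tree_e185, bc, props).set_index("edge")
    assert df.loc["left_common_carotid", "Q_mm3_s"] == pytest.approx(
        df.loc["left_subclavian", "Q_mm3_s"]
    )
    assert df.loc["pulmonary_artery_left", "Q_mm3_s"] == pytest.approx(
        df.loc["pulmonary_artery_right", "Q_mm3_s"]
    )


def test_murray_tree_has_segment_independent_shear(tree_e185):
    """Q proportional to R^3 on every edge makes tau identical everywhere."""
    props = blood_at_age(18.5)
    bc = assemble_boundaries(tree_e185, MODEL)
    df = solve_poiseuille_network(tree_e185, bc, props)
    assert np.allclose(df.tau_mPa, df.tau_mPa.iloc[0], rtol=1e-9)


def test_junction_mass_balance(tree_e185):
    props = blood_at_age(18.5)
    bc = assemble_boundaries(tree_e185, MODEL)
    df = solve_poiseuille_network(tree_e185, bc, props)
    influx = df.groupby("node_v").Q_mm3_s.sum()
    outflux = df.groupby("node_u").Q_mm3_s.sum()
    for node in set(influx.index) & set(outflux.index):
        assert influx[node] == pytest.approx(outflux[node], rel=1e-9)


def test_inconsistent_boundary_flows_rejected(tree_e185):
    props = blood_at_age(18.5)
    bc = assemble_boundaries(tree_e185, MODEL)
    bad_flows = dict(bc.outlet_flows)
    bad_flows["out_innominate"] *= 3.0
    bad = dataclasses.replace(bc, outlet_flows=bad_flows)
    with pytest.raises(ValueError, match="inconsistency|negative flow"):
        solve_poiseuille_network(tree_e185, bad, props)
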