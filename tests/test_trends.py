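"""Vessel averaging, trend statistics, and the exact Mann-Whitney test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fetalshear.blood import blood_at_age
from fetalshear.boundaries import assemble_boundaries
from fetalshear.network import solve_poiseuille_network
from fetalshear.trends import (
    mann_whitney_exact,
    trend_statistics,
    two_sample_check,
    vessel_averages,
)
from fetalshear.velocity import VelocityAgeModel, default_velocity_coeffs


@pytest.fixture(scope="module")
def network_e185(tree_e185):
    props = blood_at_age(18.5)
    model = VelocityAgeModel(coeffs=default_velocity_coeffs())
    bc = assemble_boundaries(tree_e185, model)
    return solve_poiseuille_network(tree_e185, bc, props), props


def test_uniform_field_vessel_means_equal_value(network_e185, tree_e185):
    net, props = network_e185
    uniform = net.copy()
    uniform["tau_mPa"] = 7.0
    uniform["gamma_per_s"] = 3.0
    rows = vessel_averages(uniform, tree_e185, props)
    assert np.allclose(rows.tau_mPa, 7.0)
    assert np.allclose(rows.gamma_per_s, 3.0)


def test_partition_additivity(network_e185, tree_e185):
    """Length-weighted means of two territories recombine to the global mean."""
    net, props = network_e185
    groups = {"first": ("AAo",), "second": ("DAo", "PT", "branch")}
    rows = vessel_averages(net, tree_e185, props, groups=groups).set_index("vessel")
    w = {
        v: net[net.group.isin(g)].length_mm.sum() for v, g in groups.items()
    }
    combined = sum(rows.loc[v, "tau_mPa"] * w[v] for v in groups) / sum(w.values())
    global_mean = np.average(net.tau_mPa, weights=net.length_mm)
    assert combined == pytest.approx(global_mean, rel=1e-9)


def test_empty_and_overlapping_territories_rejected(network_e185, tree_e185):
    net, props = network_e185
    with pytest.raises(ValueError, match="no flow edges"):
        vessel_averages(net, tree_e185, props, groups={"x": ("nope",)})
    with pytest.raises(ValueError, match="overlap"):
        vessel_averages(net, tree_e185, props,
                        groups={"a": ("AAo",), "b": ("AAo", "DAo")})


def test_perfect_linear_trend():
    table = pd.DataFrame(dict(age_days=[1, 2, 3, 4], tau_mPa=[2.0, 4.0, 6.0, 8.0]))
    out = trend_statistics(table, contrasts=[("tau_mPa", "age_days")])
    assert out.rho.iloc[0] == pytest.approx(1.0)
    assert out.p_zero_slope.iloc[0] < 1e-6


def test_constant_covariate_reported_undefined():
    table = pd.DataFrame(dict(age_days=[2, 2, 2], tau_mPa=[1.0, 2.0, 3.0]))
    out = trend_statistics(table, contrasts=[("tau_mPa", "age_days")])
    assert np.isnan(out.rho.iloc[0])
    assert "undefined" in out.note.iloc[0]


def test_pearson_and_slope_p_match_closed_forms():
    rng = np.random.default_rng(4)
    x = rng.normal(size=8)
    y = 0.5 * x + rng.normal(size=8)
    table = pd.DataFrame(dict(age_days=x, tau_mPa=y))
    out = trend_statistics(table, contrasts=[("tau_mPa", "age_days")])
    # brute-force Pearson
    r_brute = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
        np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
    )
    assert out.rho.iloc[0] == pytest.approx(r_brute, rel=1e-12)
    # zero-slope p from the t statistic closed form
    n = len(x)
    t = r_brute * np.sqrt((n - 2) / (1 - r_brute**2))
    p_brute = 2 * stats.t.sf(abs(t), n - 2)
    assert out.p_zero_slope.iloc[0] == pytest.approx(p_brute, rel=1e-9)


def test_identical_samples_give_p_one():
    x = [1.0, 2.0, 3.0, 4.0]
    assert mann_whitney_exact(x, list(x)) == pytest.approx(1.0)


def test_exact_permutation_matches_scipy_on_tie_free_data():
    rng = np.random.default_rng(7)
    for _ in range(6):
        x = rng.normal(size=5)
        y = rng.normal(loc=rng.uniform(-1, 1), size=6)
        ours = mann_whitney_exact(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert ours == pytest.approx(float(ref), abs=1e-12)


def test_mann_whitney_symmetry_and_bounds():
    rng = np.random.default_rng(1)
    x, y = rng.normal(size=4), rng.normal(size=5)
    p1, p2 = mann_whitney_exact(x, y), mann_whitney_exact(y, x)
    assert p1 == pytest.approx(p2)
    assert 0.0 < p1 <= 1.0
    with pytest.raises(ValueError):
        mann_whitney_exact([1.0, 2.0], [1.0, 2.0, 3.0])
    assert two_sample_check(x, y) == pytest.approx(p1)


def test_large_sample_fallback_close_to_exact():
    rng = np.random.default_rng(2)
    x = rng.normal(size=12)
    y = rng.normal(size=12)
    p_asym = mann_whitney_exact(x, y, max_enumeration=10)  # force fallback
    ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic").pvalue
    assert p_asym == pytest.approx(float(ref), rel=1e-9)
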