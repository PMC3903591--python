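"""Doppler generator and the quadratic velocity-age model."""

import numpy as np
import pandas as pd
import pytest

from fetalshear.doppler import generate_doppler
from fetalshear.velocity import (
    VelocityAgeModel,
    default_velocity_coeffs,
    fit_velocity_age,
)


def test_noiseless_records_equal_true_curve(stage_configs):
    dop = generate_doppler(stage_configs, noise_cv=0.0, measurement_cv=0.0, seed=0)
    merged = dop.records.merge(
        dop.true_curve, on=["vessel", "age_days"], suffixes=("", "_true")
    )
    assert np.allclose(merged.velocity_mm_s, merged.velocity_mm_s_true)


def test_root_velocities_equal_in_expectation(stage_configs):
    dop = generate_doppler(stage_configs, noise_cv=0.0, seed=0)
    tc = dop.true_curve.pivot(index="age_days", columns="vessel", values="velocity_mm_s")
    assert np.allclose(tc["aortic_root"], tc["pulmonary_root"])


def test_refit_recovers_coefficients_exactly_without_noise(stage_configs):
    coeffs = default_velocity_coeffs()
    dop = generate_doppler(stage_configs, eq_coeffs=coeffs, noise_cv=0.0,
                           measurement_cv=0.0, seed=0)
    model = fit_velocity_age(dop)
    assert np.allclose(model.coeffs, coeffs, rtol=1e-8)


def test_generator_determinism(stage_configs):
    a = generate_doppler(stage_configs, seed=9)
    b = generate_doppler(stage_configs, seed=9)
    pd.testing.assert_frame_equal(a.records, b.records)


def test_negative_curve_rejected(stage_configs):
    with pytest.raises(ValueError, match="non-positive"):
        generate_doppler(stage_configs, eq_coeffs=(0.0, 0.0, -5.0), seed=0)
    with pytest.raises(ValueError):
        generate_doppler(stage_configs, replicates=0, seed=0)


def test_default_curve_strictly_increasing_over_window():
    model = VelocityAgeModel(coeffs=default_velocity_coeffs())
    tt = np.linspace(14.5, 18.5, 81)
    v = model(tt)
    assert np.all(np.diff(v) > 0)
    assert np.all(v > 0)


def test_fit_requires_three_distinct_ages():
    df = pd.DataFrame(
        dict(vessel=["descending_aorta"] * 4, age_days=[14.5, 14.5, 18.5, 18.5],
             velocity_mm_s=[80, 82, 130, 131])
    )
    with pytest.raises(ValueError, match="3 distinct ages"):
        fit_velocity_age(df)


def test_monte_carlo_refit_unbiased(stage_configs):
    """200 refits at cv=0.1, n=20/age: mean coefficient bias within 2 SE of 0."""
    coeffs = np.array(default_velocity_coeffs())
    fits = []
    for k in range(200):
        dop = generate_doppler(stage_configs, noise_cv=0.1, replicates=20, seed=1000 + k)
        fits.append(fit_velocity_age(dop).coeffs)
    fits = np.array(fits)
    bias = fits.mean(axis=0) - coeffs
    se = fits.std(axis=0, ddof=1) / np.sqrt(len(fits))
    assert np.all(np.abs(bias) <= 2.0 * se)
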