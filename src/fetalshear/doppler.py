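"""Synthetic pulsed-Doppler peak-velocity measurements.

Emulates the UBM velocimetry protocol: per gestational age, a small cohort of
fetuses each contributes peak-velocity measurements at the descending aorta,
the aortic and pulmonary roots (equal in expectation, as observed), and the
proximal innominate and left common carotid arteries.

Noise model: a subject-level multiplicative lognormal factor shared by all of
one subject's vessels (inter-animal physiological variability, cv ~ 0.12 to
match the reported spread of cohort measurements) times a smaller
per-measurement lognormal error (cv ~ 0.04).  Both lognormals are mean-one, so
replicates are i.i.d. *around the true curve* and quadratic refits of the
velocity-age model are unbiased.  The noiseless ground-truth curves are
retained on the returned object for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .boundaries import assemble_boundaries
from .stages import StageConfig
from .tree import VesselTree, generate_vessel_tree
from .velocity import VelocityAgeModel, default_velocity_coeffs

SUBJECT_CV = 0.12
MEASUREMENT_CV = 0.04
#: vessels reported per subject, mapped to boundary nodes (None = DAo model)
MEASURED_VESSELS = (
    "descending_aorta",
    "aortic_root",
    "pulmonary_root",
    "innominate",
    "left_common_carotid",
)


@dataclass
class DopplerSet:
    """records: one row per (vessel, age, subject); true_curve: noiseless values."""

    records: pd.DataFrame     # vessel, age_days, subject, velocity_mm_s
    true_curve: pd.DataFrame  # vessel, age_days, velocity_mm_s
    coeffs: tuple[float, float, float]
    noise_cv: float
    seed: int


def _mean_one_lognormal(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    if cv <= 0:
        return np.ones(size if size is not None else ())
    sigma = math.sqrt(math.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def true_peak_velocities(
    tree: VesselTree, model: VelocityAgeModel | tuple, age_days: float
) -> dict[str, float]:
    """Noiseless peak velocities implied by the velocity-age curve + Murray."""
    if not callable(model):
        model = VelocityAgeModel(coeffs=tuple(model))
    bc = assemble_boundaries(tree, model, age_days)
    return {
        "descending_aorta": bc.dao_peak_velocity,
        # plug profiles at the roots: the measured peak is the plug velocity
        "aortic_root": bc.inlet_velocities["aortic_root"],
        "pulmonary_root": bc.inlet_velocities["pulmonary_root"],
        "innominate": bc.outlet_peak_velocities["out_innominate"],
        "left_common_carotid": bc.outlet_peak_velocities["out_left_common_carotid"],
    }


def generate_doppler(
    configs: list[StageConfig],
    eq_coeffs: tuple[float, float, float] | None = None,
    noise_cv: float = SUBJECT_CV,
    replicates: int = 4,
    seed: int = 0,
    measurement_cv: float = MEASUREMENT_CV,
) -> DopplerSet:
    """Generate the synthetic Doppler dataset for a list of stage configs.

    ``noise_cv`` is the total coefficient of variation of a measurement; the
    subject-shared component is sqrt(noise_cv^2 - measurement_cv^2).
    ``replicates`` is the number of subjects per age (>= 1).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    coeffs = tuple(eq_coeffs) if eq_coeffs is not None else default_velocity_coeffs()
    ages = np.array([c.age_days for c in configs])
    if np.any(np.polyval(coeffs, ages) <= 0):
        raise ValueError("velocity curve non-positive within the requested age window")
    model = VelocityAgeModel(coeffs=coeffs, t_range=(float(ages.min()), float(ages.max())))

    meas_cv = min(measurement_cv, noise_cv)
    subj_cv = math.sqrt(max(noise_cv**2 - meas_cv**2, 0.0))

    rng = np.random.default_rng(seed)
    rec_rows, true_rows = [], []
    for cfg in configs:
        tree = generate_vessel_tree(cfg)
        truth = true_peak_velocities(tree, model, cfg.age_days)
        for vessel, v in truth.items():
            true_rows.append(dict(vessel=vessel, age_days=cfg.age_days, velocity_mm_s=v))
        subj_factor = _mean_one_lognormal(rng, subj_cv, replicates)
        for j in range(replicates):
            for vessel, v in truth.items():
                eps = _mean_one_lognormal(rng, meas_cv, None)
                rec_rows.append(
                    dict(
                        vessel=vessel,
                        age_days=cfg.age_days,
                        subject=j,
                        velocity_mm_s=v * subj_factor[j] * float(eps),
                    )
                )
    return DopplerSet(
        records=pd.DataFrame(rec_rows),
        true_curve=pd.DataFrame(true_rows),
        coeffs=coeffs,
        noise_cv=noise_cv,
        seed=seed,
    )
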