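"""Velocity-age model: peak descending-aorta velocity as a quadratic in age.

Peak systolic blood velocity in the descending aorta rises with gestational
age; a second-order polynomial V(t) is fitted to Doppler measurements and used
to set flow boundary conditions at each stage.

The synthetic cohort's default ground-truth curve is defined once, from the
model's own physiology rather than ad hoc numbers: velocities scale in
proportion to R(t)/nu(t) (vessel radius over kinematic viscosity), i.e. vessel
growth keeps pace with flow demand so that wall shear stays level — the
homeostatic growth condition the downstream trend analysis is built to detect.
The absolute scale is pinned at 133 mm/s near term (E18.5), within the
published fetal-mouse UBM range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blood import blood_at_age
from .stages import AGE_MAX, AGE_MIN, dimension_scale, stage_sweep_ages

DAO_PEAK_VELOCITY_NEAR_TERM = 133.0  # mm/s at E18.5


@dataclass(frozen=True)
class VelocityAgeModel:
    """Quadratic peak-velocity model V(t) = c2 t^2 + c1 t + c0 (mm/s, t days)."""

    coeffs: tuple[float, float, float]            # (c2, c1, c0), highest first
    t_range: tuple[float, float] = (AGE_MIN, AGE_MAX)
    residual_sd: float = 0.0
    n_points: int = 0

    def __call__(self, t) -> np.ndarray | float:
        return np.polyval(self.coeffs, t)

    def __post_init__(self) -> None:
        tt = np.linspace(*self.t_range, 101)
        if np.any(np.polyval(self.coeffs, tt) <= 0):
            raise ValueError("velocity-age model must be positive over its age range")


def default_velocity_coeffs() -> tuple[float, float, float]:
    """Ground-truth quadratic for the synthetic cohort.

    Least-squares quadratic through V(t) ∝ R(t)/nu(t) at the five stages,
    scaled to 133 mm/s at E18.5.  The five shear-homeostatic values are nearly
    quadratic already, so the fit residual is well under 1%.
    """
    ages = np.array(stage_sweep_ages())
    ratio = np.array([dimension_scale(t) / blood_at_age(t).nu for t in ages])
    v = DAO_PEAK_VELOCITY_NEAR_TERM * ratio / ratio[-1]
    c = np.polyfit(ages, v, 2)
    return (float(c[0]), float(c[1]), float(c[2]))


def fit_velocity_age(
    doppler: pd.DataFrame | "object", vessel: str = "descending_aorta"
) -> VelocityAgeModel:
    """Ordinary least-squares quadratic fit of peak velocity against age.

    Accepts a DopplerSet or its records DataFrame (columns ``vessel``,
    ``age_days``, ``velocity_mm_s``).  Requires measurements at >= 3 distinct
    ages; a rank-deficient design is rejected.
    """
    records = getattr(doppler, "records", doppler)
    df = records[records["vessel"] == vessel]
    if df.empty:
        raise ValueError(f"no records for vessel {vessel!r}")
    t = df["age_days"].to_numpy(float)
    v = df["velocity_mm_s"].to_numpy(float)
    if len(np.unique(t)) < 3:
        raise ValueError("quadratic fit requires measurements at >= 3 distinct ages")
    c = np.polyfit(t, v, 2)
    resid = v - np.polyval(c, t)
    sd = float(np.sqrt(np.mean(resid**2)))
    return VelocityAgeModel(
        coeffs=(float(c[0]), float(c[1]), float(c[2])),
        t_range=(float(t.min()), float(t.max())),
        residual_sd=sd,
        n_points=len(v),
    )
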