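"""Blood properties: the hematocrit schedule and the viscosity model.

Fetal blood is treated as Newtonian, but its viscosity depends on hematocrit,
which rises over gestation.  The hematocrit schedule is linear through
(E10.5, 20%) and (term, 43.8%).  Viscosity follows an exponential hematocrit
dependence

    nu(Hct) = A * exp(B * Hct)    [cSt = mm^2/s]

with A and B fixed analytically so that the schedule reproduces the two
reference kinematic viscosities for prenatal mouse blood: 1.87 cSt at E11.5
and 2.53 cSt at E18.5.  The exponential form is the standard low-shear
hematocrit law in fetal blood rheology; anchoring it to the two published
endpoints makes the whole viscosity schedule a one-line reproducible model.

Dynamic viscosity is obtained with a fixed blood density (1.06 g/cm^3 by
default): mu [mPa s] = nu [cSt] * rho [g/cm^3].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .stages import HCT_E105, HCT_TERM, TERM_DAY, StageConfig

NU_E115 = 1.87  # cSt, kinematic viscosity anchor at E11.5
NU_E185 = 2.53  # cSt, kinematic viscosity anchor at E18.5
BLOOD_DENSITY = 1.06  # g/cm^3

#: hematocrit window within which the calibrated relation is considered valid
HCT_VALID = (0.15, 0.55)


@dataclass(frozen=True)
class BloodProperties:
    """Viscosity pair for a given hematocrit.

    mu is the dynamic viscosity in mPa s, nu the kinematic viscosity in
    cSt (mm^2/s); nu = mu / density with density in g/cm^3.
    """

    Hct: float
    mu: float       # mPa s
    nu: float       # cSt
    density: float  # g/cm^3


def hct_at_age(
    t: float,
    config: StageConfig | None = None,
    *,
    hct_early: float | None = None,
    hct_term: float | None = None,
    term_day: float | None = None,
) -> float:
    """Hematocrit fraction at gestational age ``t`` (days).

    Linear between (E10.5, 0.20) and (term_day, 0.438); ages outside
    [10.5, term_day] are rejected because the schedule is an interpolation of
    measured anchors, not a growth law.
    """
    h0 = hct_early if hct_early is not None else (config.hct_anchor_early if config else HCT_E105)
    h1 = hct_term if hct_term is not None else (config.hct_anchor_term if config else HCT_TERM)
    td = term_day if term_day is not None else (config.term_day if config else TERM_DAY)
    if not 10.5 <= t <= td:
        raise ValueError(f"gestational age t={t} outside hematocrit schedule [10.5, {td}]")
    return h0 + (h1 - h0) * (t - 10.5) / (td - 10.5)


def _calibrated_coefficients(term_day: float = TERM_DAY) -> tuple[float, float]:
    """A, B of nu = A*exp(B*Hct) pinned to the E11.5 / E18.5 viscosities."""
    h1 = hct_at_age(11.5, term_day=term_day)
    h2 = hct_at_age(18.5, term_day=term_day)
    B = math.log(NU_E185 / NU_E115) / (h2 - h1)
    A = NU_E115 / math.exp(B * h1)
    return A, B


def viscosity_from_hct(
    Hct: float, density: float = BLOOD_DENSITY, term_day: float = TERM_DAY
) -> BloodProperties:
    """Kinematic and dynamic viscosity of fetal blood at a hematocrit.

    Hct outside the calibrated validity window yields a warning but still a
    value (the exponential extrapolates smoothly).
    """
    if not 0.0 < Hct < 1.0:
        raise ValueError(f"hematocrit must be a fraction in (0,1), got {Hct}")
    if not HCT_VALID[0] <= Hct <= HCT_VALID[1]:
        warnings.warn(
            f"Hct={Hct:.3f} outside the calibrated validity window {HCT_VALID}; "
            "extrapolating the exponential relation",
            stacklevel=2,
        )
    A, B = _calibrated_coefficients(term_day)
    nu = A * math.exp(B * Hct)
    return BloodProperties(Hct=Hct, mu=nu * density, nu=nu, density=density)


def blood_at_age(t: float, config: StageConfig | None = None) -> BloodProperties:
    """Convenience composition: viscosity at the stage's hematocrit."""
    term = config.term_day if config else TERM_DAY
    return viscosity_from_hct(hct_at_age(t, config), term_day=term)
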