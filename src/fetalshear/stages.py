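"""Gestational-stage physiology for the fetal mouse great-artery model.

A :class:`StageConfig` carries the stage-dependent quantities that drive both
synthetic-data generation and the flow simulations: heart rate (and the derived
angular frequency used by the Womersley number), ejection-duration ratio, the
linear hematocrit schedule anchors, and the descending-aorta reference diameter.

Measured anchors (wildtype mouse):
  * heart rate rises linearly 216 -> 286 beats/min over E14.5 -> E18.5,
  * ejection duration (fraction of the cardiac cycle) falls 0.44 -> 0.38,
  * hematocrit is 20% at E10.5 and 43.8% at term,
  * the descending aorta is 0.573 mm wide near term (EFIC measurement).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

AGE_MIN = 14.5
AGE_MAX = 18.5

HEART_RATE_E145 = 216.0  # beats/min
HEART_RATE_E185 = 286.0
EJECTION_RATIO_E145 = 0.44
EJECTION_RATIO_E185 = 0.38

HCT_E105 = 0.20        # hematocrit fraction at E10.5
HCT_TERM = 0.438       # hematocrit fraction at term
TERM_DAY = 19.5        # mouse term (default convention; configurable)

DAO_DIAMETER_NEAR_TERM = 0.573  # mm, near-term descending-aorta width
#: fraction of the near-term dimension that vessels have at E14.5
DIMENSION_SCALE_E145 = 0.55


def dimension_scale(age_days: float) -> float:
    """Linear growth factor applied to all vessel dimensions.

    1.0 at E18.5, ``DIMENSION_SCALE_E145`` at E14.5 (so cross-sectional areas
    roughly triple over the stage window, matching the observed monotone growth
    of lumen areas with gestational age).
    """
    return DIMENSION_SCALE_E145 + (1.0 - DIMENSION_SCALE_E145) * (age_days - AGE_MIN) / (
        AGE_MAX - AGE_MIN
    )


@dataclass(frozen=True)
class StageConfig:
    """Stage-indexed physiology driving generation and simulation."""

    age_days: float
    heart_rate: float                 # beats/min
    ejection_ratio: float             # systolic fraction of the cycle
    hct_anchor_early: float = HCT_E105
    hct_anchor_term: float = HCT_TERM
    term_day: float = TERM_DAY
    dao_diameter: float = DAO_DIAMETER_NEAR_TERM  # mm, near-term anchor
    seed: int = 0

    # derived
    omega: float = field(init=False)  # angular frequency of heart rate, rad/s

    def __post_init__(self) -> None:
        if not 0.0 < self.ejection_ratio < 1.0:
            raise ValueError(f"ejection_ratio must be in (0,1), got {self.ejection_ratio}")
        if not 0.0 < self.hct_anchor_early < 1.0 or not 0.0 < self.hct_anchor_term < 1.0:
            raise ValueError("hematocrit anchors must be fractions in (0,1)")
        object.__setattr__(self, "omega", 2.0 * math.pi * self.heart_rate / 60.0)


def make_stage_config(age_days: float, seed: int = 0, **overrides) -> StageConfig:
    """Build the default stage configuration at a gestational age.

    Heart rate and ejection ratio are linearly interpolated between the E14.5
    and E18.5 anchors.  Ages outside [14.5, 18.5] are rejected: the measured
    anchors do not extrapolate.
    """
    if not AGE_MIN <= age_days <= AGE_MAX:
        raise ValueError(
            f"age_days={age_days} outside the modelled window "
            f"[{AGE_MIN}, {AGE_MAX}] (E14.5-E18.5)"
        )
    frac = (age_days - AGE_MIN) / (AGE_MAX - AGE_MIN)
    hr = HEART_RATE_E145 + frac * (HEART_RATE_E185 - HEART_RATE_E145)
    ej = EJECTION_RATIO_E145 + frac * (EJECTION_RATIO_E185 - EJECTION_RATIO_E145)
    kwargs = dict(age_days=age_days, heart_rate=hr, ejection_ratio=ej, seed=seed)
    kwargs.update(overrides)
    return StageConfig(**kwargs)


def stage_sweep_ages() -> list[float]:
    """The five stages analysed throughout: E14.5 ... E18.5."""
    return [14.5, 15.5, 16.5, 17.5, 18.5]
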