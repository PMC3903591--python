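"""End-to-end stage sweep: the complete E14.5-E18.5 analysis pipeline.

For each of the five gestational stages this generates the synthetic tree and
Doppler cohort, fits the velocity-age quadratic to the pooled descending-aorta
measurements, assembles Murray's-law boundary conditions with stage-matched
blood properties, solves the reduced-order flow network, and accumulates:

* the per-vessel trend table (mean wall shear stress/rate, centerline
  velocity, lumen area, Reynolds number per territory and stage),
* the trend statistics (Pearson rho, zero-slope p) against age and size,
* the Murray-validation comparison: branch velocities predicted from each
  subject's descending-aorta measurement alone versus that subject's directly
  "measured" branch velocities, per age and branch artery (exact Mann-Whitney),
* the maximum centerline-averaged Reynolds number over all vessels and stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blood import blood_at_age
from .boundaries import assemble_boundaries
from .doppler import DopplerSet, generate_doppler
from .network import solve_poiseuille_network
from .stages import StageConfig, make_stage_config, stage_sweep_ages
from .tree import generate_vessel_tree
from .trends import mann_whitney_exact, trend_statistics, vessel_averages
from .velocity import VelocityAgeModel, fit_velocity_age

#: branch arteries compared against direct Doppler in the Murray validation
VALIDATION_BRANCHES = {
    "innominate": "out_innominate",
    "left_common_carotid": "out_left_common_carotid",
}


@dataclass
class SweepResult:
    configs: list[StageConfig]
    doppler: DopplerSet
    model: VelocityAgeModel
    trend_table: pd.DataFrame
    trend_stats: pd.DataFrame
    murray_validation: pd.DataFrame   # age_days, vessel, p_value, n
    networks: dict = field(default_factory=dict)  # age -> network DataFrame

    @property
    def max_Re(self) -> float:
        return float(self.trend_table["Re"].max())

    def tau_relative_spread(self) -> float:
        t = self.trend_table["tau_mPa"]
        return float((t.max() - t.min()) / t.mean())

    def area_growth_factor(self) -> float:
        by_age = self.trend_table.groupby("age_days")["area_mm2"].mean()
        return float(by_age.iloc[-1] / by_age.iloc[0])


def run_stage_sweep(
    seed: int = 0,
    ages: list[float] | None = None,
    replicates: int = 4,
    noise_cv: float = 0.12,
    velocity_model: str = "canonical",
) -> SweepResult:
    """Run the full synthetic-cohort analysis across gestational stages.

    ``velocity_model``: 'canonical' drives the boundary conditions with the
    single velocity-age quadratic of the study (the published-curve procedure:
    one fitted curve sets all stages' flows), which makes the trend table a
    deterministic function of the growth law; 'fit' re-fits the quadratic to
    this sweep's own noisy Doppler cohort instead.  The Murray validation
    always compares against the noisy per-subject measurements.
    """
    ages = ages if ages is not None else stage_sweep_ages()
    configs = [
        make_stage_config(t, seed=seed + 17 * i) for i, t in enumerate(ages)
    ]
    doppler = generate_doppler(
        configs, noise_cv=noise_cv, replicates=replicates, seed=seed
    )
    if velocity_model == "canonical":
        from .velocity import default_velocity_coeffs

        model = VelocityAgeModel(coeffs=default_velocity_coeffs())
    elif velocity_model == "fit":
        model = fit_velocity_age(doppler)
    else:
        raise ValueError(f"unknown velocity_model {velocity_model!r}")

    rows = []
    networks = {}
    validation_rows = []
    for cfg in configs:
        tree = generate_vessel_tree(cfg)
        props = blood_at_age(cfg.age_days, cfg)
        bc = assemble_boundaries(tree, model, cfg.age_days)
        net = solve_poiseuille_network(tree, bc, props)
        networks[cfg.age_days] = net
        rows.append(vessel_averages(net, tree, props))

        # Murray validation: per-subject predicted branch velocity from the
        # subject's own DAo measurement + Murray's law, vs direct measurement
        rec = doppler.records
        dao = rec[(rec.vessel == "descending_aorta") & (rec.age_days == cfg.age_days)]
        dao = dao.sort_values("subject")["velocity_mm_s"].to_numpy()
        for vessel, node in VALIDATION_BRANCHES.items():
            ratio = (
                bc.outlet_peak_velocities[node] / bc.dao_peak_velocity
            )  # deterministic Murray map, independent of the measurements
            predicted = dao * ratio
            measured = rec[(rec.vessel == vessel) & (rec.age_days == cfg.age_days)]
            measured = measured.sort_values("subject")["velocity_mm_s"].to_numpy()
            p = mann_whitney_exact(predicted, measured)
            validation_rows.append(
                dict(age_days=cfg.age_days, vessel=vessel, p_value=p, n=len(dao))
            )

    trend_table = pd.concat(rows, ignore_index=True)
    stats_df = trend_statistics(trend_table)
    return SweepResult(
        configs=configs,
        doppler=doppler,
        model=model,
        trend_table=trend_table,
        trend_stats=stats_df,
        murray_validation=pd.DataFrame(validation_rows),
        networks=networks,
    )
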