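"""Per-vessel stage trends and the accompanying statistics.

The trend analysis averages wall shear stress, wall shear rate, centerline
velocity and lumen area within three vessel territories — the ascending aorta
(proximal to the aortic isthmus, including the arch), the descending aorta,
and the pulmonary trunk analysed together with the ductus arteriosus — and
examines their trends against gestational age and against vessel size.
Correlations are Pearson's rho; trend significance is the p-value for the
hypothesis that the regression slope is zero, computed cumulatively over all
vessels.  Two-sample comparisons (simulated vs measured branch velocities)
use the Mann-Whitney U test with exact permutation enumeration at the small
group sizes of fetal cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .blood import BloodProperties
from .tree import VesselTree

#: vessel territories: trend-table vessel name -> flow-edge groups included
VESSEL_GROUPS = {
    "AAo": ("AAo",),
    "DAo": ("DAo",),
    "PT+ductus": ("PT",),
}

#: the (quantity, covariate) contrasts reported by the trend analysis
DEFAULT_CONTRASTS = [
    ("tau_mPa", "age_days"),
    ("gamma_per_s", "age_days"),
    ("V_c_mm_s", "age_days"),
    ("area_mm2", "age_days"),
    ("tau_mPa", "area_mm2"),
    ("gamma_per_s", "area_mm2"),
    ("V_c_mm_s", "area_mm2"),
]


def vessel_averages(
    network_df: pd.DataFrame,
    tree: VesselTree,
    props: BloodProperties,
    age_days: float | None = None,
    groups: dict | None = None,
) -> pd.DataFrame:
    """Length-weighted vessel means of tau, gamma, V_c and area per territory.

    Operates on the reduced-order network solution; each flow edge contributes
    with weight equal to its length.  Raises if a requested territory has no
    edges (overlap/coverage errors surface as empty or double-counted groups
    upstream).
    """
    if age_days is None:
        age_days = tree.config.age_days
    groups = groups or VESSEL_GROUPS
    seen: set[str] = set()
    rows = []
    for vessel, grps in groups.items():
        sub = network_df[network_df["group"].isin(grps)]
        if sub.empty:
            raise ValueError(f"vessel territory {vessel!r} matched no flow edges")
        overlap = seen.intersection(sub["edge"])
        if overlap:
            raise ValueError(f"vessel territories overlap on edges {sorted(overlap)}")
        seen.update(sub["edge"])
        w = sub["length_mm"].to_numpy(float)
        w = w / w.sum()
        rows.append(
            dict(
                vessel=vessel,
                age_days=age_days,
                tau_mPa=float(np.dot(w, sub["tau_mPa"])),
                gamma_per_s=float(np.dot(w, sub["gamma_per_s"])),
                V_c_mm_s=float(np.dot(w, sub["V_max_mm_s"])),
                area_mm2=float(np.dot(w, np.pi * sub["radius_mm"] ** 2)),
                Re=float(np.dot(w, sub["V_max_mm_s"] * sub["radius_mm"] / props.nu)),
            )
        )
    return pd.DataFrame(rows)


def trend_statistics(
    table: pd.DataFrame, contrasts: list[tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Pearson rho and zero-slope regression p for each contrast.

    Pooled across vessels (all rows enter each contrast).  A constant
    covariate makes the correlation undefined; it is reported as NaN with a
    note rather than raising.
    """
    contrasts = contrasts or DEFAULT_CONTRASTS
    out = []
    for qty, cov in contrasts:
        if qty not in table.columns or cov not in table.columns:
            raise KeyError(f"trend table lacks column {qty!r} or {cov!r}")
        x = table[cov].to_numpy(float)
        y = table[qty].to_numpy(float)
        if len(x) < 3:
            raise ValueError("need >= 3 rows per contrast")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out.append(dict(quantity=qty, covariate=cov, rho=np.nan,
                            slope=np.nan, p_zero_slope=np.nan,
                            note="constant input: correlation undefined"))
            continue
        rho, _ = stats.pearsonr(x, y)
        reg = stats.linregress(x, y)
        out.append(dict(quantity=qty, covariate=cov, rho=float(rho),
                        slope=float(reg.slope), p_zero_slope=float(reg.pvalue),
                        note=""))
    return pd.DataFrame(out)


# ----------------------------------------------------- Mann-Whitney U test

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of sample x vs y with the midrank tie convention."""
    u = 0.0
    for xi in x:
        u += np.sum(xi > y) + 0.5 * np.sum(xi == y)
    return float(u)


def mann_whitney_exact(x, y, max_enumeration: int = 400_000) -> float:
    """Two-sided Mann-Whitney p by exact permutation enumeration.

    Enumerates all C(n1+n2, n1) group assignments when that count is within
    ``max_enumeration`` (it always is at fetal-cohort group sizes), counting
    assignments whose U deviates from its null mean at least as much as the
    observed one.  Ties are handled naturally by the enumeration (midranks).
    Falls back to the normal approximation with tie correction for large
    samples.  Requires >= 3 observations per group.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 < 3 or n2 < 3:
        raise ValueError("need >= 3 samples per group")
    if math.comb(n1 + n2, n1) > max_enumeration:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        return float(res.pvalue)
    pooled = np.concatenate([x, y])
    mu = n1 * n2 / 2.0
    obs = abs(_u_statistic(x, y) - mu)
    count = 0
    total = 0
    idx_all = range(n1 + n2)
    for pick in combinations(idx_all, n1):
        sel = np.zeros(n1 + n2, bool)
        sel[list(pick)] = True
        u = _u_statistic(pooled[sel], pooled[~sel])
        if abs(u - mu) >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


def two_sample_check(simulated, measured) -> float:
    """Rank-test p that simulated and measured values share a distribution."""
    return mann_whitney_exact(simulated, measured)
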