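"""Wall shear fields and unwrapped (arclength x azimuth) shear maps.

Wall shear rate gamma is the normal gradient of the tangential velocity at
the wall; wall shear stress tau = mu * gamma.  Shear is reported as a
magnitude (non-negative).  Maps are laid out as the shear-map figures:
distance from the vessel root on one axis, circumferential angle on the
other, with holes masked at branch ostia and the azimuth origin fixed to a
configured anatomical direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blood import BloodProperties
from .deanflow import CurvedTubeSolution
from .pipeflow import PipeFlowSolution


@dataclass
class WallShearField:
    """Tidy per-wall-sample shear data.

    ``samples`` columns: segment, arclength_mm, azimuth_deg, gamma_per_s,
    tau_mPa.  tau = mu * gamma holds identically by construction.
    """

    samples: pd.DataFrame
    mu: float    # mPa s

    def mean_tau(self) -> float:
        return float(self.samples["tau_mPa"].mean())

    def mean_gamma(self) -> float:
        return float(self.samples["gamma_per_s"].mean())


def wall_shear(
    solution: PipeFlowSolution | CurvedTubeSolution | pd.DataFrame,
    props: BloodProperties,
    nphi: int = 36,
    segment: str = "",
) -> WallShearField:
    """Wall shear rate/stress samples from a flow solution.

    * PipeFlowSolution: gamma(z) from the one-sided wall gradient, replicated
      around the (axisymmetric) circumference.
    * CurvedTubeSolution: axial Poiseuille shear combined with the secondary
      Dean contribution, as a function of azimuth (uniform in arclength).
    * Poiseuille-network DataFrame: one uniform value per edge.
    """
    phis = np.linspace(0.0, 360.0, nphi, endpoint=False)
    rows = []
    if isinstance(solution, PipeFlowSolution):
        gam = solution.wall_shear_rate()
        for z, g in zip(solution.z, gam):
            g = abs(float(g))
            for p in phis:
                rows.append((segment or "tube", float(z), float(p), g))
    elif isinstance(solution, CurvedTubeSolution):
        # axial contribution -dw/dr|wall = 4 v_mean / R; secondary u_phi wall
        # gradient from the streamfunction mode
        g_ax = 4.0 * solution.v_mean / solution.R
        h = solution.s[1] - solution.s[0]
        fpp_wall = (
            2.0 * solution.f[-1] - 5.0 * solution.f[-2] + 4.0 * solution.f[-3]
            - solution.f[-4]
        ) / h**2
        nz = 8
        for iz in range(nz):
            zloc = iz / max(nz - 1, 1)
            for p in phis:
                g_sec = abs(fpp_wall * np.sin(np.deg2rad(p))) / solution.R**2
                g = float(np.hypot(g_ax, g_sec))
                rows.append((segment or "curved_tube", zloc, float(p), g))
    elif isinstance(solution, pd.DataFrame):
        s0 = 0.0
        for _, r in solution.iterrows():
            for p in phis:
                rows.append((r["edge"], s0 + r["length_mm"] / 2.0, float(p),
                             float(r["gamma_per_s"])))
    else:
        raise TypeError(f"unsupported solution type {type(solution)!r}")
    df = pd.DataFrame(rows, columns=["segment", "arclength_mm", "azimuth_deg", "gamma_per_s"])
    if df.empty:
        raise ValueError("no wall samples produced (wall patch absent?)")
    df["tau_mPa"] = props.mu * df["gamma_per_s"]
    return WallShearField(samples=df, mu=props.mu)


@dataclass
class UnwrappedMap:
    """Shear map over (arclength, azimuth) with ostial holes masked."""

    arclength: np.ndarray      # bin centers, mm
    azimuth: np.ndarray        # bin centers, deg in [0, 360)
    values: np.ndarray         # (n_arc, n_phi), NaN in holes/empty bins
    hole_mask: np.ndarray      # True where a branch ostium punches through
    orientation_key: str = "right half = superior/dorsal surface"

    def masked_mean(self) -> float:
        ok = ~self.hole_mask & np.isfinite(self.values)
        return float(self.values[ok].mean())

    @property
    def holes(self) -> int:
        """Number of connected hole regions (periodic in azimuth)."""
        from scipy import ndimage

        mask = self.hole_mask
        if not mask.any():
            return 0
        # roll the azimuth axis so an all-empty column sits at the seam; then
        # plain labelling respects the periodicity
        empty_cols = np.flatnonzero(~mask.any(axis=0))
        if len(empty_cols):
            mask = np.roll(mask, -int(empty_cols[0]), axis=1)
            _, n = ndimage.label(mask)
            return int(n)
        # no empty column: label with union of seam-adjacent labels
        lab, n = ndimage.label(mask)
        seam_pairs = {
            (int(a), int(b))
            for a, b in zip(lab[:, 0], lab[:, -1])
            if a > 0 and b > 0 and a != b
        }
        merged = n
        parent = {i: i for i in range(1, n + 1)}

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for a, b in seam_pairs:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
                merged -= 1
        return int(merged)


def unwrap_map(
    wall: WallShearField,
    n_arc: int = 60,
    n_phi: int = 36,
    holes: list[tuple[float, float, float]] | None = None,
    value: str = "tau_mPa",
    azimuth_origin_deg: float = 0.0,
    hole_halfwidth_deg: float = 30.0,
    orientation_key: str = "right half = superior/dorsal surface",
) -> UnwrappedMap:
    """Bin wall samples onto a rectangular (arclength, azimuth) grid.

    ``holes``: (arclength_mm, azimuth_deg, radius_mm) per branch ostium; bins
    within +-radius_mm in arclength and +-``hole_halfwidth_deg`` in azimuth of
    the ostium are masked out.  ``azimuth_origin_deg`` rotates the map so the
    configured anatomical direction sits at azimuth 0.
    """
    df = wall.samples
    s = df["arclength_mm"].to_numpy(float)
    a = np.mod(df["azimuth_deg"].to_numpy(float) - azimuth_origin_deg, 360.0)
    v = df[value].to_numpy(float)
    s_edges = np.linspace(s.min(), s.max() + 1e-12, n_arc + 1)
    a_edges = np.linspace(0.0, 360.0, n_phi + 1)
    num, _, _ = np.histogram2d(s, a, bins=[s_edges, a_edges], weights=v)
    cnt, _, _ = np.histogram2d(s, a, bins=[s_edges, a_edges])
    with np.errstate(invalid="ignore"):
        grid = np.where(cnt > 0, num / np.maximum(cnt, 1), np.nan)
    s_c = 0.5 * (s_edges[:-1] + s_edges[1:])
    a_c = 0.5 * (a_edges[:-1] + a_edges[1:])
    hole_mask = np.zeros_like(grid, dtype=bool)
    for (hs, ha, hr) in holes or []:
        ha = np.mod(ha - azimuth_origin_deg, 360.0)
        for i, sc in enumerate(s_c):
            for j, ac in enumerate(a_c):
                dang = min(abs(ac - ha), 360.0 - abs(ac - ha))
                if (abs(sc - hs) <= hr) and (dang <= hole_halfwidth_deg):
                    hole_mask[i, j] = True
    grid = np.where(hole_mask, np.nan, grid)
    return UnwrappedMap(
        arclength=s_c, azimuth=a_c, values=grid, hole_mask=hole_mask,
        orientation_key=orientation_key,
    )
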