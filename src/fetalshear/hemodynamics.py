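"""Centerline dimensionless numbers and normalized helicity.

Reynolds number along a vessel centerline:  Re = V_c * a / nu, with V_c the
centerline velocity, ``a`` the average of the maximum and minimum
cross-sectional radii at the station, and nu the kinematic viscosity.
Womersley number: alpha = a * sqrt(omega / nu) with omega the angular
frequency of the heart rate.  Normalized helicity: the cosine of the angle
between velocity and vorticity, Hn = (V . w)/(|V||w|) in [-1, 1], zero where
either magnitude is below a degeneracy floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blood import BloodProperties
from .centerline import Centerline
from .fields import FlowField
from .stages import StageConfig

HELICITY_FLOOR = 1e-9


def reynolds(V_c, a, nu) -> np.ndarray | float:
    """Re = V_c a / nu (radius-based)."""
    return np.asarray(V_c) * np.asarray(a) / nu


def womersley(a, omega, nu) -> np.ndarray | float:
    """alpha = a sqrt(omega / nu)."""
    return np.asarray(a) * np.sqrt(omega / nu)


@dataclass
class CenterlineHemodynamics:
    """Per-station V_c, Re and alpha along one centerline."""

    table: pd.DataFrame   # columns: s_mm, V_c_mm_s, a_mm, Re, alpha, flagged

    def mean_Re(self) -> float:
        return float(self.table["Re"].mean())

    def max_Re(self) -> float:
        return float(self.table["Re"].max())


def centerline_hemodynamics(
    V_c: np.ndarray | float,
    centerline: Centerline,
    props: BloodProperties,
    config: StageConfig,
    stations: np.ndarray | None = None,
) -> CenterlineHemodynamics:
    """Evaluate Re and alpha at centerline stations.

    ``V_c`` is the centerline velocity per station (mm/s), or a scalar applied
    everywhere (fully developed segments).  Radii come from the centerline's
    inscribed-sphere record.
    """
    if stations is None:
        stations = centerline.arclength
    stations = np.atleast_1d(np.asarray(stations, float))
    _, _, a = centerline.at(stations)
    v = np.broadcast_to(np.atleast_1d(np.asarray(V_c, float)), stations.shape)
    if np.any(v < 0):
        raise ValueError("centerline velocities must be non-negative")
    re = reynolds(v, a, props.nu)
    al = womersley(a, config.omega, props.nu)
    return CenterlineHemodynamics(
        table=pd.DataFrame(
            dict(s_mm=stations, V_c_mm_s=v, a_mm=a, Re=re, alpha=al)
        )
    )


@dataclass
class HelicityField:
    """Normalized helicity per interior sample of a flow field."""

    hn: np.ndarray
    field: FlowField
    floor: float = HELICITY_FLOOR

    def positive_integral(self) -> float:
        w = self.field.weights if self.field.weights is not None else np.ones_like(self.hn)
        return float((w * np.clip(self.hn, 0.0, None)).sum())

    def negative_integral(self) -> float:
        w = self.field.weights if self.field.weights is not None else np.ones_like(self.hn)
        return float((w * np.clip(-self.hn, 0.0, None)).sum())

    def chirality_imbalance(self) -> float:
        """|pos - neg| / max(pos, neg) of the two chirality volume integrals."""
        p, n = self.positive_integral(), self.negative_integral()
        return abs(p - n) / max(p, n, 1e-300)


def normalized_helicity(field: FlowField, floor: float = HELICITY_FLOOR) -> HelicityField:
    """Hn = (V . w) / (|V| |w|), zeroed where either magnitude < floor."""
    v = field.velocity
    w = field.vorticity
    vmag = np.linalg.norm(v, axis=1)
    wmag = np.linalg.norm(w, axis=1)
    dot = np.einsum("ij,ij->i", v, w)
    hn = np.zeros(len(v))
    ok = (vmag > floor) & (wmag > floor)
    np.divide(dot, vmag * wmag, out=hn, where=ok)
    hn = np.clip(hn, -1.0, 1.0)
    return HelicityField(hn=hn, field=field, floor=floor)
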