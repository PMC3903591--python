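"""Small differential-geometry helpers shared by the generators and morphometry.

Everything operates on polylines sampled from parametric centerlines: tangents,
cumulative arclength, and rotation-minimizing frames (used both to sweep
elliptical tube sections and to give unwrapped shear maps a twist-free azimuth).
"""

from __future__ import annotations

import numpy as np


def polyline_arclength(points: np.ndarray) -> np.ndarray:
    """Cumulative arclength of an (N,3) polyline, starting at 0."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def polyline_tangents(points: np.ndarray) -> np.ndarray:
    """Unit tangents of an (N,3) polyline (central differences)."""
    t = np.gradient(points, axis=0)
    n = np.linalg.norm(t, axis=1, keepdims=True)
    n[n == 0] = 1.0
    return t / n


def rotation_minimizing_frames(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Twist-free orthonormal frames along a polyline.

    Returns (tangents, n1, n2), each (N,3).  Uses the double-reflection method,
    which transports the initial normal with no spurious rotation about the
    tangent — important for azimuth continuity in unwrapped maps.
    """
    pts = np.asarray(points, dtype=float)
    t = polyline_tangents(pts)
    n = len(pts)
    n1 = np.zeros_like(pts)
    # initial normal: any unit vector orthogonal to t[0]
    a = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(a, t[0])) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    v = a - np.dot(a, t[0]) * t[0]
    n1[0] = v / np.linalg.norm(v)
    for i in range(n - 1):
        v1 = pts[i + 1] - pts[i]
        c1 = np.dot(v1, v1)
        if c1 == 0:
            n1[i + 1] = n1[i]
            continue
        rL = n1[i] - (2.0 / c1) * np.dot(v1, n1[i]) * v1
        tL = t[i] - (2.0 / c1) * np.dot(v1, t[i]) * v1
        v2 = t[i + 1] - tL
        c2 = np.dot(v2, v2)
        if c2 == 0:
            n1[i + 1] = rL
        else:
            n1[i + 1] = rL - (2.0 / c2) * np.dot(v2, rL) * v2
        # re-orthonormalize against accumulated numerical drift
        n1[i + 1] -= np.dot(n1[i + 1], t[i + 1]) * t[i + 1]
        n1[i + 1] /= np.linalg.norm(n1[i + 1])
    n2 = np.cross(t, n1)
    return t, n1, n2


def sample_arc(
    center: np.ndarray,
    radius: float,
    u: np.ndarray,
    v: np.ndarray,
    theta0: float,
    theta1: float,
    n: int,
) -> np.ndarray:
    """Sample a circular arc c + R(u cos(th) + v sin(th)) at n points."""
    th = np.linspace(theta0, theta1, n)
    return (
        np.asarray(center)[None, :]
        + radius * (np.cos(th)[:, None] * np.asarray(u)[None, :]
                    + np.sin(th)[:, None] * np.asarray(v)[None, :])
    )


def sample_hermite(
    p0: np.ndarray, p1: np.ndarray, t0: np.ndarray, t1: np.ndarray, n: int
) -> np.ndarray:
    """Cubic Hermite curve from p0 (tangent t0) to p1 (tangent t1), n samples.

    Tangents are scaled by the chord length, which gives gentle, non-looping
    curves for the junction geometries used here.
    """
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    chord = np.linalg.norm(p1 - p0)
    m0 = np.asarray(t0, float) / np.linalg.norm(t0) * chord
    m1 = np.asarray(t1, float) / np.linalg.norm(t1) * chord
    s = np.linspace(0.0, 1.0, n)[:, None]
    h00 = 2 * s**3 - 3 * s**2 + 1
    h10 = s**3 - 2 * s**2 + s
    h01 = -2 * s**3 + 3 * s**2
    h11 = s**3 - s**2
    return h00 * p0 + h10 * m0 + h01 * p1 + h11 * m1


def resample_polyline(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a polyline uniformly in arclength."""
    s = polyline_arclength(points)
    snew = np.linspace(0.0, s[-1], n)
    out = np.empty((n, 3))
    for k in range(3):
        out[:, k] = np.interp(snew, s, points[:, k])
    return out


def min_polyline_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum point-to-point distance between two sampled polylines."""
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    return float(d.min())
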