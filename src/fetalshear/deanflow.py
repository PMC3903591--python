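"""Dean secondary flow in gently curved tubes, and passive-tracer transport.

In a tube of radius R bent with centerline radius Rc >> R, centrifugal forcing
of the axial (Poiseuille) flow drives a weak secondary circulation in the
cross-section: the classical Dean flow of two counter-rotating cells, mirror
images across the curvature plane.  At the low Dean numbers of the fetal great
arteries the secondary flow obeys the linearized (perturbation) balance

    grad^4 psi = -(1/(nu Rc)) d(w^2)/dy ,   w(s) = 2 v_mean (1 - s^2)

with no-slip, clamped boundary conditions, where psi is the in-plane
streamfunction, s = r/R, and y is the coordinate normal to the curvature
plane.  Separating the single Fourier mode psi = f(s) sin(phi) reduces this to
a 1D biharmonic two-point boundary-value problem, solved here with
second-order finite differences; Dean's closed-form series solution of the
same problem is the independent oracle in the test suite.

The same module quantifies streamline order: passive tracers released in the
two halves of the inlet cross-section are advected with the composed
(axial + secondary) velocity field; because the secondary streamfunction
vanishes on the curvature plane, the two streams cannot cross it — the model
explanation for the observed absence of mixing downstream of the ductus
insertion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .blood import BloodProperties
from .fields import FlowField


def dean_number(R: float, Rc: float, v_mean: float, nu: float) -> float:
    """De = Re * sqrt(R/Rc) with Re = 2 v_mean R / nu (diameter-based)."""
    return 2.0 * v_mean * R / nu * np.sqrt(R / Rc)


def solve_dean_mode(ns: int, C: float = 1.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Solve L1 L1 f = C s (1 - s^2) on [0,1], f(0)=f(1)=f'(1)=0.

    L1 is the m=1 Fourier-mode radial operator f'' + f'/s - f/s^2.  Returns
    (s, f, g) with g = L1 f (needed for the axial vorticity).  Solved as a
    coupled sparse system in (f, g) with second-order differences.
    """
    if ns < 8:
        raise ValueError("ns too small for a meaningful biharmonic solve")
    s = np.linspace(0.0, 1.0, ns)
    h = s[1] - s[0]
    n = ns
    N = 2 * n  # unknowns: f (0..n-1), g (n..2n-1)
    rows, cols, vals = [], [], []
    rhs = np.zeros(N)

    def add(r_, c_, v_):
        rows.append(r_); cols.append(c_); vals.append(v_)

    def l1_row(row, base, j):
        sj = s[j]
        add(row, base + j + 1, 1.0 / h**2 + 1.0 / (2.0 * h * sj))
        add(row, base + j, -2.0 / h**2 - 1.0 / sj**2)
        add(row, base + j - 1, 1.0 / h**2 - 1.0 / (2.0 * h * sj))

    # f block: f(0)=0 ; interior: L1 f - g = 0 ; f(1)=0
    add(0, 0, 1.0)
    for j in range(1, n - 1):
        l1_row(j, 0, j)
        add(j, n + j, -1.0)
    add(n - 1, n - 1, 1.0)
    # g block: g(0)=0 ; interior: L1 g = C s (1-s^2) ; last row: f'(1)=0
    add(n, n, 1.0)
    for j in range(1, n - 1):
        l1_row(n + j, n, j)
        rhs[n + j] = C * s[j] * (1.0 - s[j] ** 2)
    add(2 * n - 1, n - 1, 3.0 / (2.0 * h))
    add(2 * n - 1, n - 2, -4.0 / (2.0 * h))
    add(2 * n - 1, n - 3, 1.0 / (2.0 * h))

    A = sp.csc_matrix((vals, (rows, cols)), shape=(N, N))
    x = spla.spsolve(A, rhs)
    return s, x[:n], x[n:]


@dataclass
class CurvedTubeSolution:
    """Fully developed flow in a gently curved tube (loose-coiling limit)."""

    R: float          # tube radius, mm
    Rc: float         # centerline bend radius, mm
    v_mean: float     # bulk axial velocity, mm/s
    nu: float         # kinematic viscosity, mm^2/s
    s: np.ndarray     # radial grid r/R
    f: np.ndarray     # secondary-streamfunction mode, mm^2/s
    g: np.ndarray     # L1 f (axial-vorticity mode), mm^2/s

    @property
    def dean(self) -> float:
        return dean_number(self.R, self.Rc, self.v_mean, self.nu)

    def axial_velocity(self, s) -> np.ndarray:
        return 2.0 * self.v_mean * (1.0 - np.asarray(s) ** 2)

    def _f_interp(self, s):
        return np.interp(s, self.s, self.f)

    def _fprime(self) -> np.ndarray:
        if not hasattr(self, "_fprime_cache"):
            object.__setattr__(self, "_fprime_cache", np.gradient(self.f, self.s))
        return self._fprime_cache

    def secondary_velocity(self, s, phi) -> tuple[np.ndarray, np.ndarray]:
        """(u_x, u_y) in cross-plane coordinates, x toward the outer wall.

        u_r = f cos(phi) / (R s), u_phi = -f' sin(phi) / R; the s -> 0 limit
        uses f'(0).
        """
        s = np.asarray(s, float)
        phi = np.asarray(phi, float)
        fp = np.interp(s, self.s, self._fprime())
        fv = self._f_interp(s)
        with np.errstate(divide="ignore", invalid="ignore"):
            u_s = np.where(s > 1e-12, fv / (self.R * np.maximum(s, 1e-300)), fp / self.R)
        u_phi = -fp * np.sin(phi) / self.R
        u_s = u_s * np.cos(phi)
        u_x = u_s * np.cos(phi) - u_phi * np.sin(phi)
        u_y = u_s * np.sin(phi) + u_phi * np.cos(phi)
        return u_x, u_y

    def cross_section_field(
        self, ns_out: int = 24, nphi: int = 48
    ) -> dict[str, np.ndarray]:
        """Velocity/vorticity components on a polar cross-section grid.

        Returns dict with s, phi (1D), and 2D arrays (ns_out, nphi): w (axial),
        u_x, u_y (secondary), zeta (axial vorticity), om_x, om_y (in-plane
        vorticity from the axial shear), hn (normalized helicity).
        """
        sg = np.linspace(0.0, 1.0, ns_out)
        ph = np.linspace(0.0, 2.0 * np.pi, nphi, endpoint=False)
        S, P = np.meshgrid(sg, ph, indexing="ij")
        w = self.axial_velocity(S)
        u_x, u_y = self.secondary_velocity(S, P)
        gv = np.interp(sg, self.s, self.g)
        zeta = -(gv[:, None] / self.R**2) * np.sin(P)
        wp = -4.0 * self.v_mean * S           # dw/ds
        om_x = wp * np.sin(P) / self.R
        om_y = -wp * np.cos(P) / self.R
        hdot = u_x * om_x + u_y * om_y + w * zeta
        vmag = np.sqrt(u_x**2 + u_y**2 + w**2)
        omag = np.sqrt(om_x**2 + om_y**2 + zeta**2)
        floor = 1e-9
        ok = (vmag > floor) & (omag > floor)
        hn = np.zeros_like(hdot)
        np.divide(hdot, vmag * omag, out=hn, where=ok)
        return dict(s=sg, phi=ph, w=w, u_x=u_x, u_y=u_y, zeta=zeta,
                    om_x=om_x, om_y=om_y, hn=hn)

    def to_flow_field(
        self,
        arc_angle: float = np.pi / 2,
        nz: int = 12,
        ns_out: int = 16,
        nphi: int = 36,
    ) -> FlowField:
        """Embed the fully developed solution along a circular arc in 3D.

        The arc lies in the x-z plane (curvature plane y = 0 of the global
        frame corresponds to the cross-section's x axis).  Volume quadrature
        weights include the torus metric (1 + (R s / Rc) cos(phi)).
        """
        cs = self.cross_section_field(ns_out, nphi)
        sg, ph = cs["s"], cs["phi"]
        th = np.linspace(0.0, arc_angle, nz)
        pts, vel, vort, wts, wall = [], [], [], [], []
        dth = arc_angle / max(nz - 1, 1)
        ds = sg[1] - sg[0]
        dph = ph[1] - ph[0]
        for t in th:
            # centerline point and frame on the arc (center at origin)
            c = self.Rc * np.array([np.cos(t), 0.0, np.sin(t)])
            tang = np.array([-np.sin(t), 0.0, np.cos(t)])
            ex = np.array([np.cos(t), 0.0, np.sin(t)])   # outward (away from bend center)
            ey = np.array([0.0, 1.0, 0.0])               # normal to curvature plane
            for i, sv in enumerate(sg):
                for j, pv in enumerate(ph):
                    x_loc = self.R * sv * np.cos(pv)
                    y_loc = self.R * sv * np.sin(pv)
                    pts.append(c + x_loc * ex + y_loc * ey)
                    v = cs["u_x"][i, j] * ex + cs["u_y"][i, j] * ey + cs["w"][i, j] * tang
                    o = cs["om_x"][i, j] * ex + cs["om_y"][i, j] * ey + cs["zeta"][i, j] * tang
                    vel.append(v)
                    vort.append(o)
                    metric = 1.0 + (self.R * sv / self.Rc) * np.cos(pv)
                    wts.append(self.R * sv * ds * self.R * dph * self.Rc * dth * metric)
                    wall.append(i == len(sg) - 1)
        return FlowField(
            points=np.array(pts),
            velocity=np.array(vel),
            vorticity=np.array(vort),
            weights=np.array(wts),
            wall_mask=np.array(wall),
            meta=dict(
                kind="curved_tube", shape=(nz, len(sg), len(ph)), R=self.R,
                Rc=self.Rc, v_mean=self.v_mean, nu=self.nu, dean=self.dean,
            ),
        )


def solve_curved_tube(
    R: float, Rc: float, v_mean: float, props: BloodProperties | float, ns: int = 201
) -> CurvedTubeSolution:
    """Solve the low-Dean secondary flow for a curved tube.

    Valid in the loose-coiling, low-Dean regime (R/Rc small, De below ~20);
    the fetal arch configurations used here sit well inside it.
    """
    nu = props.nu if hasattr(props, "nu") else float(props)
    if Rc <= R:
        raise ValueError("bend radius Rc must exceed tube radius R")
    W = 2.0 * v_mean
    C = 4.0 * W**2 * R**3 / (nu * Rc)
    s, f, g = solve_dean_mode(ns, C)
    return CurvedTubeSolution(R=R, Rc=Rc, v_mean=v_mean, nu=nu, s=s, f=f, g=g)


def trace_mixing(
    sol: CurvedTubeSolution,
    length: float,
    n_particles: int = 400,
    seed: int = 0,
    dt_factor: float = 0.02,
) -> float:
    """Fraction of tracers that cross the curvature plane over a tube length.

    Particles seeded uniformly over the inlet section (excluding a thin wall
    layer), labelled by the half-plane (sign of y) they start in — the model of
    the arch and ductus streams meeting in the descending aorta.  Advection is
    RK4 in the cross-plane combined with axial transport at the local axial
    velocity.  Returns the mixing fraction (label changes at the exit).
    """
    rng = np.random.default_rng(seed)
    # uniform over the disk up to 0.9 R (the wall layer barely advects), in mm
    rr = 0.9 * sol.R * np.sqrt(rng.uniform(0.0, 1.0, n_particles))
    th = rng.uniform(0.0, 2.0 * np.pi, n_particles)
    x = rr * np.cos(th)
    y = rr * np.sin(th)
    off = 0.005 * sol.R
    y = np.where(np.abs(y) < off, off * np.sign(y + 1e-300), y)
    start_sign = np.sign(y)

    # time step resolves the (slow) secondary turnover; axial position only
    # accumulates transit, so it does not constrain dt
    sec_speed = max(np.abs(sol.f).max() / sol.R, 1e-12)
    dt = dt_factor * sol.R / sec_speed

    def vel(x_mm, y_mm):
        s = np.minimum(np.sqrt(x_mm**2 + y_mm**2) / sol.R, 1.0)
        phi = np.arctan2(y_mm, x_mm)
        ux, uy = sol.secondary_velocity(s, phi)
        return ux, uy, sol.axial_velocity(s)

    zpos = np.zeros(n_particles)
    active = np.ones(n_particles, dtype=bool)
    # straggler cap: particles stuck in the near-wall layer never cross the
    # symmetry plane anyway; stop after several bulk transit times
    max_steps = int(10.0 * (length / sol.v_mean) / dt) + 1
    for _ in range(max_steps):
        if not active.any():
            break
        xs, ys = x[active], y[active]
        k1 = vel(xs, ys)
        k2 = vel(xs + 0.5 * dt * k1[0], ys + 0.5 * dt * k1[1])
        k3 = vel(xs + 0.5 * dt * k2[0], ys + 0.5 * dt * k2[1])
        k4 = vel(xs + dt * k3[0], ys + dt * k3[1])
        x[active] = xs + dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        y[active] = ys + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        zpos[active] += dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        active &= zpos < length
    mixed = np.sign(y) != start_sign
    return float(mixed.mean())
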