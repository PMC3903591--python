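"""Steady axisymmetric incompressible Navier-Stokes solver for straight tubes.

Streamfunction-vorticity formulation on a uniform (z, r) grid.  With the
Stokes streamfunction psi (u_z = psi_r / r, u_r = -psi_z / r) and azimuthal
vorticity w = du_r/dz - du_z/dr, the steady equations are

    E^2 psi = -r w,                      E^2 = d_zz + d_rr - (1/r) d_r
    u_r w_r + u_z w_z - (u_r/r) w = nu (w_rr + w_r/r - w/r^2 + w_zz)

Boundary conditions: plug (or parabolic) inflow, no-slip wall with Thom's
wall-vorticity closure, symmetry on the axis, fully developed outflow.  The
nonlinear system is solved by Picard iteration with under-relaxation; each
sub-problem is a sparse direct solve.  Mass conservation is built in: the
volumetric flux at any station is 2 pi psi_wall, which is imposed exactly.

This regime (Re <= 100, laminar, steady) is the one the fetal great arteries
occupy; the solver is validated against the Poiseuille closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .blood import BloodProperties


class ConvergenceError(RuntimeError):
    """Raised when the Picard iteration does not reach tolerance."""

    def __init__(self, msg: str, residuals: list[float]):
        super().__init__(msg)
        self.residuals = residuals


@dataclass
class PipeFlowSolution:
    """Converged axisymmetric field on the (z, r) grid."""

    R: float                 # tube radius, mm
    L: float                 # tube length, mm
    r: np.ndarray            # (nr,)
    z: np.ndarray            # (nz,)
    u_z: np.ndarray          # (nz, nr) mm/s
    u_r: np.ndarray          # (nz, nr) mm/s
    psi: np.ndarray          # (nz, nr) mm^3/s (Stokes streamfunction)
    omega: np.ndarray        # (nz, nr) 1/s (azimuthal vorticity)
    v_mean: float            # bulk velocity, mm/s
    nu: float                # kinematic viscosity, mm^2/s
    residuals: list[float] = field(default_factory=list)

    def flux(self, iz: int = -1) -> float:
        """Volumetric flow (mm^3/s) through station iz (Simpson on r u_z).

        Note the formulation conserves mass exactly in the discrete sense
        (flux = 2 pi (psi_wall - psi_axis) is imposed); this velocity-based
        integral is the independent post-processing check of that property.
        """
        from scipy.integrate import simpson

        return float(2.0 * np.pi * simpson(self.u_z[iz] * self.r, x=self.r))

    def flux_streamfunction(self, iz: int = -1) -> float:
        """Exact discrete flux 2 pi (psi_wall - psi_axis), mm^3/s."""
        return float(2.0 * np.pi * (self.psi[iz, -1] - self.psi[iz, 0]))

    def wall_shear_rate(self) -> np.ndarray:
        """gamma(z) = -du_z/dr at the wall, second-order one-sided, 1/s."""
        h = self.r[1] - self.r[0]
        return -(3.0 * self.u_z[:, -1] - 4.0 * self.u_z[:, -2] + self.u_z[:, -3]) / (2.0 * h)

    def reynolds(self) -> float:
        """Centerline-velocity Reynolds number V_c a / nu at the exit."""
        return float(self.u_z[-1, 0] * self.R / self.nu)


def poiseuille_profile(r: np.ndarray, R: float, v_mean: float) -> np.ndarray:
    """Closed-form fully developed profile u(r) = 2 v_mean (1 - (r/R)^2)."""
    return 2.0 * v_mean * (1.0 - (np.asarray(r) / R) ** 2)


def solve_pipe(
    R: float,
    L: float,
    v_mean: float,
    props: BloodProperties | float,
    nr: int = 33,
    nz: int = 121,
    inlet: str = "plug",
    tol: float = 1e-6,
    max_iter: int = 600,
    relax: float = 0.35,
) -> PipeFlowSolution:
    """Solve steady developing flow in a straight tube of radius R, length L.

    ``props`` may be a BloodProperties or a kinematic viscosity in mm^2/s.
    ``inlet`` is 'plug' (uniform) or 'parabolic'.  Converges when the maximum
    relative change of the velocity field between Picard iterates falls below
    ``tol``; raises ConvergenceError (with the residual history) otherwise.
    """
    nu = props.nu if hasattr(props, "nu") else float(props)
    if v_mean <= 0 or R <= 0 or L <= 0 or nu <= 0:
        raise ValueError("R, L, v_mean and viscosity must be positive")
    r = np.linspace(0.0, R, nr)
    z = np.linspace(0.0, L, nz)
    hr = r[1] - r[0]
    hz = z[1] - z[0]

    if inlet == "plug":
        psi_in = 0.5 * v_mean * r**2
        omega_in = np.zeros(nr)
    elif inlet == "parabolic":
        psi_in = v_mean * (r**2 - 0.5 * r**4 / R**2)
        omega_in = 4.0 * v_mean * r / R**2  # -du/dr of the parabolic profile
    else:
        raise ValueError(f"unknown inlet profile {inlet!r}")
    psi_wall = 0.5 * v_mean * R**2

    def idx(i, j):  # i: z index, j: r index
        return i * nr + j

    n_unknown = nz * nr

    # --- assemble the psi operator once (it is linear and fixed) -------------
    rows, cols, vals, rhs_template = [], [], [], np.zeros(n_unknown)
    for i in range(nz):
        for j in range(nr):
            k = idx(i, j)
            if i == 0:  # inlet: Dirichlet
                rows.append(k); cols.append(k); vals.append(1.0)
                rhs_template[k] = psi_in[j]
            elif j == 0:  # axis
                rows.append(k); cols.append(k); vals.append(1.0)
            elif j == nr - 1:  # wall
                rows.append(k); cols.append(k); vals.append(1.0)
                rhs_template[k] = psi_wall
            elif i == nz - 1:  # outlet: d psi / dz = 0
                rows += [k, k]; cols += [k, idx(i - 1, j)]; vals += [1.0, -1.0]
            else:
                rj = r[j]
                rows += [k] * 5
                cols += [k, idx(i + 1, j), idx(i - 1, j), idx(i, j + 1), idx(i, j - 1)]
                vals += [
                    -2.0 / hz**2 - 2.0 / hr**2,
                    1.0 / hz**2,
                    1.0 / hz**2,
                    1.0 / hr**2 - 1.0 / (2.0 * hr * rj),
                    1.0 / hr**2 + 1.0 / (2.0 * hr * rj),
                ]
    A_psi = sp.csc_matrix((vals, (rows, cols)), shape=(n_unknown, n_unknown))
    psi_lu = spla.splu(A_psi)

    # --- initial guess: plug flow everywhere ---------------------------------
    psi = np.tile(psi_in, (nz, 1))
    omega = np.zeros((nz, nr))
    u_z = np.full((nz, nr), v_mean)
    u_z[:, -1] = 0.0
    u_r = np.zeros((nz, nr))

    def velocities(psi):
        uz = np.empty((nz, nr))
        ur = np.zeros((nz, nr))
        dpsi_dr = np.gradient(psi, hr, axis=1)
        dpsi_dz = np.gradient(psi, hz, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            uz[:, 1:] = dpsi_dr[:, 1:] / r[1:][None, :]
            ur[:, 1:] = -dpsi_dz[:, 1:] / r[1:][None, :]
        uz[:, 0] = 2.0 * psi[:, 1] / hr**2  # psi ~ u r^2/2 near the axis
        uz[:, -1] = 0.0                     # no slip (exact)
        ur[:, 0] = 0.0
        return uz, ur

    residuals: list[float] = []
    scale = max(v_mean, 1e-30)
    for it in range(max_iter):
        # Thom wall vorticity from current psi
        om_wall = 2.0 * (psi[:, -1] - psi[:, -2]) / (hr**2 * R)

        # ---- vorticity transport: sparse upwind system ----------------------
        rows, cols, vals = [], [], []
        rhs = np.zeros(n_unknown)
        for i in range(nz):
            for j in range(nr):
                k = idx(i, j)
                if i == 0:                # inlet: profile vorticity
                    rows.append(k); cols.append(k); vals.append(1.0)
                    rhs[k] = omega_in[j]
                elif j == 0:              # axis: omega = 0
                    rows.append(k); cols.append(k); vals.append(1.0)
                elif j == nr - 1:         # wall: Thom closure
                    rows.append(k); cols.append(k); vals.append(1.0)
                    rhs[k] = om_wall[i]
                elif i == nz - 1:         # outlet: d omega / dz = 0
                    rows += [k, k]; cols += [k, idx(i - 1, j)]; vals += [1.0, -1.0]
                else:
                    rj = r[j]
                    az, ar = u_z[i, j], u_r[i, j]
                    diag = 2.0 * nu / hz**2 + 2.0 * nu / hr**2 + nu / rj**2 - ar / rj
                    czp = -nu / hz**2
                    czm = -nu / hz**2
                    crp = -nu / hr**2 - nu / (2.0 * hr * rj)
                    crm = -nu / hr**2 + nu / (2.0 * hr * rj)
                    # first-order upwind convection
                    if az >= 0:
                        diag += az / hz; czm += -az / hz
                    else:
                        diag += -az / hz; czp += az / hz
                    if ar >= 0:
                        diag += ar / hr; crm += -ar / hr
                    else:
                        diag += -ar / hr; crp += ar / hr
                    rows += [k] * 5
                    cols += [k, idx(i + 1, j), idx(i - 1, j), idx(i, j + 1), idx(i, j - 1)]
                    vals += [diag, czp, czm, crp, crm]
        A_om = sp.csc_matrix((vals, (rows, cols)), shape=(n_unknown, n_unknown))
        omega_new = spla.spsolve(A_om, rhs).reshape(nz, nr)
        omega = relax * omega_new + (1.0 - relax) * omega

        # ---- streamfunction solve -------------------------------------------
        rhs_psi = rhs_template.copy()
        for i in range(1, nz - 1):
            for j in range(1, nr - 1):
                rhs_psi[idx(i, j)] = -r[j] * omega[i, j]
        psi_new = psi_lu.solve(rhs_psi).reshape(nz, nr)
        psi = relax * psi_new + (1.0 - relax) * psi

        u_z_new, u_r_new = velocities(psi)
        res = float(
            max(np.abs(u_z_new - u_z).max(), np.abs(u_r_new - u_r).max()) / scale
        )
        u_z, u_r = u_z_new, u_r_new
        residuals.append(res)
        if res < tol:
            break
    else:
        raise ConvergenceError(
            f"pipe solver did not converge in {max_iter} iterations "
            f"(last residual {residuals[-1]:.3e})",
            residuals,
        )

    return PipeFlowSolution(
        R=R, L=L, r=r, z=z, u_z=u_z, u_r=u_r, psi=psi, omega=omega,
        v_mean=v_mean, nu=nu, residuals=residuals,
    )
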