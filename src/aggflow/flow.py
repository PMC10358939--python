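"""Steady incompressible Navier-Stokes flow with a Brinkman (Darcy) drag.

The momentum balance solved here is

    rho * (du/dt + u . grad u) = -grad p + mu * lap u - (mu / k) u + f,
    div u = 0,

on a uniform staggered (MAC) voxel grid: velocity components live on cell
faces, pressure at cell centers, so the discrete divergence constraint can
be enforced exactly.  The spatially varying Darcy coefficient
``sigma_D = mu / k`` represents the porous platelet aggregate; it is zero in
the free lumen and spans many orders of magnitude inside the aggregate, so
it is treated implicitly per cell (factor ``1 / (1 + dt sigma_D / rho)``)
while advection and diffusion are explicit.

Steady state is reached by a pseudo-time march with an incremental-pressure
projection: each step advances momentum with the current pressure gradient,
then solves a Poisson problem for the pressure *increment* and projects the
velocity onto the divergence-free space.  Because the pressure gradient
enters the momentum update before the per-cell Darcy division, the fixed
point of the iteration satisfies the exact discrete steady momentum balance
even where ``dt * sigma_D / rho >> 1``.  The Poisson solve is an exact FFT
diagonalization of the discrete Laplacian (DCT-II across the walls, DCT-IV
along the streamwise axis for the inlet-Neumann / outlet-Dirichlet pair),
so every step enforces incompressibility to round-off.

Channel boundary conditions: a parabolic inlet profile with prescribed wall
shear rate, constant pressure (zero-gradient velocity) at the outlet,
no-slip at the top and bottom walls, and free-slip symmetry (or optional
periodicity) on the lateral faces.  Units are mm-g-s; pressure is then
numerically in Pa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft

from .imaging import VoxelGrid
from .porous import AggregateField

__all__ = [
    "PhysicalParams",
    "BoundaryConditions",
    "SolverSettings",
    "FlowField",
    "ConvergenceReport",
    "NonConvergenceError",
    "inlet_profile",
    "assemble_darcy_coefficient",
    "solve_steady",
    "check_divergence",
]


@dataclass(frozen=True)
class PhysicalParams:
    """Fluid and platelet parameters (mm-g-s units).

    Defaults: whole-blood density 1.025e-3 g/mm^3 and viscosity 3e-3
    g/(mm s), activated-platelet sphericity 0.71 and diameter 2e-3 mm (which
    doubles as the Peclet characteristic length), pseudo-time step 1e-5 s.
    """

    rho: float = 1.025e-3
    mu: float = 3e-3
    sphericity: float = 0.71
    d_p: float = 2e-3
    dt: float = 1e-5

    def __post_init__(self):
        if min(self.rho, self.mu, self.sphericity, self.d_p, self.dt) <= 0:
            raise ValueError("all physical parameters must be strictly positive")

    @property
    def nu(self) -> float:
        return self.mu / self.rho


@dataclass(frozen=True)
class BoundaryConditions:
    """Channel boundary conditions.

    ``gamma_w`` is the wall shear rate (1/s) of the inlet parabola and
    ``height`` the channel height H (mm).  Inlet is the y = 0 face, outlet
    y = Ly, no-slip walls at z = 0 and z = H; the lateral x faces are
    ``"slip"`` (free-slip symmetry, default) or ``"periodic"``.
    ``body_force`` is a uniform force density (g mm^-2 s^-2), used e.g. to
    drive fully developed porous-channel flow; for such flows
    ``inlet_velocity`` (a callable v(z) in mm/s) overrides the parabola.
    """

    gamma_w: float
    height: float
    lateral: str = "slip"
    body_force: tuple[float, float, float] = (0.0, 0.0, 0.0)
    inlet_velocity: object = None

    def __post_init__(self):
        if self.gamma_w < 0:
            raise ValueError("wall shear rate must be non-negative")
        if self.height <= 0:
            raise ValueError("channel height must be positive")
        if self.lateral not in ("slip", "periodic"):
            raise ValueError("lateral condition must be 'slip' or 'periodic'")

    @property
    def v_max(self) -> float:
        """Peak of the inlet parabola, gamma_w * H / 4 (mm/s)."""
        return self.gamma_w * self.height / 4.0

    @property
    def v_ref(self) -> float:
        return self.v_max


@dataclass(frozen=True)
class SolverSettings:
    """Pseudo-time march controls.

    The march stops once the relative max-norm velocity change per step has
    stayed below ``tol`` for ``window`` consecutive steps.  ``advection
    = False`` drops the nonlinear term entirely (Stokes mode), making the
    solution exactly linear in the wall shear rate.
    """

    tol: float = 1e-6
    window: int = 100
    div_tol: float = 1e-3
    max_steps: int = 200_000
    advection: bool = True
    relax: float = 1.0
    history_every: int = 50

    def __post_init__(self):
        if self.tol <= 0 or self.div_tol <= 0:
            raise ValueError("tolerances must be positive")
        if not (0.0 < self.relax <= 1.0):
            raise ValueError("under-relaxation factor must lie in (0, 1]")


@dataclass
class ConvergenceReport:
    converged: bool
    steps: int
    dt: float
    final_residual: float
    residual_history: list = field(default_factory=list)
    message: str = ""


class NonConvergenceError(RuntimeError):
    """Raised when the pseudo-time march fails; carries the report."""

    def __init__(self, message: str, report: ConvergenceReport):
        super().__init__(message)
        self.report = report


@dataclass
class FlowField:
    """Staggered MAC velocity (mm/s) and cell-centered pressure (Pa).

    ``u`` lives on x faces ``(nx+1, ny, nz)``, ``v`` on y faces
    ``(nx, ny+1, nz)``, ``w`` on z faces ``(nx, ny, nz+1)``, ``p`` on cells.
    """

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    p: np.ndarray
    grid: VoxelGrid
    v_ref: float = 1.0

    def cell_center_velocity(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        uc = 0.5 * (self.u[:-1] + self.u[1:])
        vc = 0.5 * (self.v[:, :-1] + self.v[:, 1:])
        wc = 0.5 * (self.w[:, :, :-1] + self.w[:, :, 1:])
        return uc, vc, wc

    def speed(self) -> np.ndarray:
        uc, vc, wc = self.cell_center_velocity()
        return np.sqrt(uc * uc + vc * vc + wc * wc)

    def divergence(self) -> np.ndarray:
        return (np.diff(self.u, axis=0) + np.diff(self.v, axis=1)
                + np.diff(self.w, axis=2)) / self.grid.h

    def inlet_flux(self) -> float:
        return float(self.v[:, 0, :].sum()) * self.grid.h ** 2

    def outlet_flux(self) -> float:
        return float(self.v[:, -1, :].sum()) * self.grid.h ** 2

    def flux_mismatch(self) -> float:
        """|outlet - inlet| / |inlet| volumetric flux (dimensionless)."""
        qin, qout = self.inlet_flux(), self.outlet_flux()
        if qin == 0:
            return abs(qout)
        return abs(qout - qin) / abs(qin)


def inlet_profile(bc: BoundaryConditions, grid: VoxelGrid) -> np.ndarray:
    """Inlet streamwise velocity v(z) = (gamma_w / H) z (H - z), uniform in x.

    The wall slope dv/dz at z = 0 is exactly ``gamma_w``; the peak is
    ``gamma_w H / 4`` at mid-height and the cross-section mean is two thirds
    of the peak.
    """
    nx, _, nz = grid.shape
    z = grid.cell_centers(2)
    if bc.inlet_velocity is not None:
        prof = np.asarray(bc.inlet_velocity(z), dtype=float)
    else:
        prof = (bc.gamma_w / bc.height) * z * (bc.height - z)
    return np.broadcast_to(prof[None, :], (nx, nz)).copy()


def assemble_darcy_coefficient(agg: AggregateField, params: PhysicalParams) -> np.ndarray:
    """Cell-centered sigma_D = mu/k on occupied cells, 0 elsewhere."""
    return agg.darcy_coefficient(params.mu)


def _harm(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Harmonic mean, defined as 0 when either argument is 0 (so the
    aggregate surface acquires no spurious drag from averaging alone)."""
    s = a + b
    out = np.zeros(np.broadcast(a, b).shape)
    pos = (a > 0) & (b > 0)
    out[pos] = 2.0 * a[pos] * b[pos] / s[pos]
    return out


class _PoissonFFT:
    """Exact solver for the projection Poisson problem on the MAC grid.

    Staggered Neumann conditions across both walls and both lateral faces,
    Neumann at the inlet and Dirichlet (p = 0 on the face) at the outlet;
    the corresponding 1D operators are diagonalized by DCT-II, DCT-II (or a
    real FFT when the lateral direction is periodic) and DCT-IV.  The
    outlet Dirichlet condition removes the constant-pressure null space, so
    the operator is nonsingular.
    """

    def __init__(self, grid: VoxelGrid, lateral: str = "slip"):
        nx, ny, nz = grid.shape
        h = grid.h
        self.periodic = lateral == "periodic"
        if self.periodic:
            kx = 2.0 * np.cos(2.0 * np.pi * np.arange(nx // 2 + 1) / nx) - 2.0
        else:
            kx = 2.0 * np.cos(np.pi * np.arange(nx) / nx) - 2.0
        ky = 2.0 * np.cos(np.pi * (np.arange(ny) + 0.5) / ny) - 2.0
        kz = 2.0 * np.cos(np.pi * np.arange(nz) / nz) - 2.0
        self._lam = (kx[:, None, None] + ky[None, :, None] + kz[None, None, :]) / h ** 2

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        a = sfft.dct(rhs, type=2, axis=2, norm="ortho")
        a = sfft.dct(a, type=4, axis=1, norm="ortho")
        if self.periodic:
            a = sfft.rfft(a, axis=0)
        else:
            a = sfft.dct(a, type=2, axis=0, norm="ortho")
        a = a / self._lam
        if self.periodic:
            a = sfft.irfft(a, n=rhs.shape[0], axis=0)
        else:
            a = sfft.idct(a, type=2, axis=0, norm="ortho")
        a = sfft.idct(a, type=4, axis=1, norm="ortho")
        return sfft.idct(a, type=2, axis=2, norm="ortho")


def _stable_dt(params: PhysicalParams, bc: BoundaryConditions, h: float) -> float:
    """Requested dt, reduced to the explicit diffusive / advective limits."""
    dt_diff = 0.8 * params.rho * h * h / (6.0 * params.mu)
    u_est = 1.5 * bc.v_max
    u_est += (abs(bc.body_force[0]) + abs(bc.body_force[1])) * bc.height ** 2 / (8.0 * params.mu)
    dt_adv = 0.4 * h / u_est if u_est > 0 else np.inf
    return min(params.dt, dt_diff, dt_adv)


# --- ghost padding --------------------------------------------------------
# Tangential walls use reflection (ghost = -interior) so the no-slip value
# sits on the wall; the outlet copies the last interior plane (zero
# gradient); free-slip mirrors the tangential component (zero shear).


def _pad_u(u):
    Up = np.empty((u.shape[0], u.shape[1] + 2, u.shape[2] + 2))
    Up[:, 1:-1, 1:-1] = u
    Up[:, 0, 1:-1] = -u[:, 0, :]
    Up[:, -1, 1:-1] = u[:, -1, :]
    Up[:, :, 0] = -Up[:, :, 1]
    Up[:, :, -1] = -Up[:, :, -2]
    return Up


def _pad_v(v, periodic):
    Vp = np.empty((v.shape[0] + 2, v.shape[1], v.shape[2] + 2))
    Vp[1:-1, :, 1:-1] = v
    if periodic:
        Vp[0, :, 1:-1] = v[-1]
        Vp[-1, :, 1:-1] = v[0]
    else:
        Vp[0, :, 1:-1] = v[0]
        Vp[-1, :, 1:-1] = v[-1]
    Vp[:, :, 0] = -Vp[:, :, 1]
    Vp[:, :, -1] = -Vp[:, :, -2]
    return Vp


def _pad_w(w, periodic):
    Wp = np.empty((w.shape[0] + 2, w.shape[1] + 2, w.shape[2]))
    Wp[1:-1, 1:-1, :] = w
    if periodic:
        Wp[0, 1:-1, :] = w[-1]
        Wp[-1, 1:-1, :] = w[0]
    else:
        Wp[0, 1:-1, :] = w[0]
        Wp[-1, 1:-1, :] = w[-1]
    Wp[:, 0, :] = -Wp[:, 1, :]
    Wp[:, -1, :] = Wp[:, -2, :]
    return Wp


def _lap(Ap, center, h2):
    return (Ap[2:, 1:-1, 1:-1] + Ap[:-2, 1:-1, 1:-1]
            + Ap[1:-1, 2:, 1:-1] + Ap[1:-1, :-2, 1:-1]
            + Ap[1:-1, 1:-1, 2:] + Ap[1:-1, 1:-1, :-2]
            - 6.0 * center) / h2


def _advection_u(u, v, w, Up, h):
    dudx = (u[2:] - u[:-2]) / (2 * h)
    dudy = (Up[1:-1, 2:, 1:-1] - Up[1:-1, :-2, 1:-1]) / (2 * h)
    dudz = (Up[1:-1, 1:-1, 2:] - Up[1:-1, 1:-1, :-2]) / (2 * h)
    vbar = 0.25 * (v[:-1, :-1, :] + v[:-1, 1:, :] + v[1:, :-1, :] + v[1:, 1:, :])
    wbar = 0.25 * (w[:-1, :, :-1] + w[:-1, :, 1:] + w[1:, :, :-1] + w[1:, :, 1:])
    return u[1:-1] * dudx + vbar * dudy + wbar * dudz


def _advection_v(u, v, w, Vp, h):
    dvdx = (Vp[2:, 1:-1, 1:-1] - Vp[:-2, 1:-1, 1:-1]) / (2 * h)
    dvdy = (v[:, 2:, :] - v[:, :-2, :]) / (2 * h)
    dvdz = (Vp[1:-1, 1:-1, 2:] - Vp[1:-1, 1:-1, :-2]) / (2 * h)
    ubar = 0.25 * (u[:-1, :-1, :] + u[1:, :-1, :] + u[:-1, 1:, :] + u[1:, 1:, :])
    wbar = 0.25 * (w[:, :-1, :-1] + w[:, :-1, 1:] + w[:, 1:, :-1] + w[:, 1:, 1:])
    return ubar * dvdx + v[:, 1:-1, :] * dvdy + wbar * dvdz


def _advection_w(u, v, w, Wp, h):
    dwdx = (Wp[2:, 1:-1, 1:-1] - Wp[:-2, 1:-1, 1:-1]) / (2 * h)
    dwdy = (Wp[1:-1, 2:, 1:-1] - Wp[1:-1, :-2, 1:-1]) / (2 * h)
    dwdz = (w[:, :, 2:] - w[:, :, :-2]) / (2 * h)
    ubar = 0.25 * (u[:-1, :, :-1] + u[1:, :, :-1] + u[:-1, :, 1:] + u[1:, :, 1:])
    vbar = 0.25 * (v[:, :-1, :-1] + v[:, 1:, :-1] + v[:, :-1, 1:] + v[:, 1:, 1:])
    return ubar * dwdx + vbar * dwdy + w[:, :, 1:-1] * dwdz


def solve_steady(params: PhysicalParams, bc: BoundaryConditions,
                 sigma: np.ndarray, grid: VoxelGrid,
                 settings: SolverSettings | None = None,
                 ) -> tuple[FlowField, ConvergenceReport]:
    """March the projection scheme to steady state.

    ``sigma`` is the cell-centered Darcy coefficient lattice
    (g mm^-3 s^-1), zero in the free lumen; it is harmonically averaged onto
    faces.  Returns the converged ``FlowField`` and a ``ConvergenceReport``;
    raises ``NonConvergenceError`` (with the residual history attached) if
    the march exceeds ``max_steps`` or produces non-finite values.
    """
    if settings is None:
        settings = SolverSettings()
    nx, ny, nz = grid.shape
    if min(nx, ny, nz) < 2:
        raise ValueError("the flow grid needs at least 2 cells per axis")
    if abs(nz * grid.h - bc.height) > 1e-9 * bc.height:
        raise ValueError("grid vertical extent must equal the channel height")
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != grid.shape:
        raise ValueError("Darcy coefficient lattice must live on the flow grid")
    if not np.isfinite(sigma).all() or sigma.min() < 0:
        raise ValueError("Darcy coefficient must be finite and non-negative")

    h = grid.h
    h2 = h * h
    rho, nu = params.rho, params.nu
    dt = _stable_dt(params, bc, h)
    periodic = bc.lateral == "periodic"
    fx, fy, fz = (g / rho for g in bc.body_force)

    # face-averaged Darcy factors for the per-cell implicit treatment
    if periodic:
        sig_u = _harm(np.roll(sigma, 1, axis=0), sigma)        # all nx u-faces
    else:
        sig_u = _harm(sigma[:-1], sigma[1:])                   # interior faces
    sig_v = _harm(sigma[:, :-1], sigma[:, 1:])
    sig_w = _harm(sigma[:, :, :-1], sigma[:, :, 1:])
    den_u = 1.0 + dt * sig_u / rho
    den_v = 1.0 + dt * sig_v / rho
    den_w = 1.0 + dt * sig_w / rho

    poisson = _PoissonFFT(grid, bc.lateral)
    prof = inlet_profile(bc, grid)

    # initial guess: undisturbed channel flow everywhere
    u = np.zeros((nx + 1, ny, nz))
    v = np.broadcast_to(prof[:, None, :], (nx, ny + 1, nz)).copy()
    w = np.zeros((nx, ny, nz + 1))
    p = np.zeros((nx, ny, nz))

    history: list[tuple[int, float]] = []
    below = 0
    resid = np.inf
    relax = settings.relax
    coef = dt / (rho * h)

    for step in range(1, settings.max_steps + 1):
        Up = _pad_u(u)
        Vp = _pad_v(v, periodic)
        Wp = _pad_w(w, periodic)

        lap_v = _lap(Vp, v[:, 1:-1, :], h2)
        lap_w = _lap(Wp, w[:, :, 1:-1], h2)
        if settings.advection:
            adv_v = _advection_v(u, v, w, Vp, h)
            adv_w = _advection_w(u, v, w, Wp, h)
        else:
            adv_v = adv_w = 0.0
        dpdy = np.diff(p, axis=1) / h
        dpdz = np.diff(p, axis=2) / h
        v_star = (v[:, 1:-1, :] + dt * (nu * lap_v - adv_v + fy - dpdy / rho)) / den_v
        w_star = (w[:, :, 1:-1] + dt * (nu * lap_w - adv_w + fz - dpdz / rho)) / den_w

        un = u.copy()
        vn = v.copy()
        wn = w.copy()
        if periodic:
            ue = u[:-1]
            uxm = np.roll(ue, 1, axis=0)
            uxp = np.roll(ue, -1, axis=0)
            lap_u = ((uxm + uxp - 2.0 * ue) / h2
                     + (Up[:-1, 2:, 1:-1] + Up[:-1, :-2, 1:-1] - 2.0 * ue) / h2
                     + (Up[:-1, 1:-1, 2:] + Up[:-1, 1:-1, :-2] - 2.0 * ue) / h2)
            if settings.advection:
                dudx = (uxp - uxm) / (2 * h)
                dudy = (Up[:-1, 2:, 1:-1] - Up[:-1, :-2, 1:-1]) / (2 * h)
                dudz = (Up[:-1, 1:-1, 2:] - Up[:-1, 1:-1, :-2]) / (2 * h)
                vxm = np.roll(v, 1, axis=0)
                wxm = np.roll(w, 1, axis=0)
                vbar = 0.25 * (vxm[:, :-1] + vxm[:, 1:] + v[:, :-1] + v[:, 1:])
                wbar = 0.25 * (wxm[:, :, :-1] + wxm[:, :, 1:]
                               + w[:, :, :-1] + w[:, :, 1:])
                adv_u = ue * dudx + vbar * dudy + wbar * dudz
            else:
                adv_u = 0.0
            dpdx = (p - np.roll(p, 1, axis=0)) / h
            u_star = (ue + dt * (nu * lap_u - adv_u + fx - dpdx / rho)) / den_u
            un[:-1] = ue + relax * (u_star - ue)
            un[-1] = un[0]
        else:
            lap_u = _lap(Up, u[1:-1], h2)
            adv_u = _advection_u(u, v, w, Up, h) if settings.advection else 0.0
            dpdx = np.diff(p, axis=0) / h
            u_star = (u[1:-1] + dt * (nu * lap_u - adv_u + fx - dpdx / rho)) / den_u
            un[1:-1] = u[1:-1] + relax * (u_star - u[1:-1])
            un[0] = 0.0
            un[-1] = 0.0

        vn[:, 1:-1] = v[:, 1:-1] + relax * (v_star - v[:, 1:-1])
        wn[:, :, 1:-1] = w[:, :, 1:-1] + relax * (w_star - w[:, :, 1:-1])
        vn[:, 0] = prof
        vn[:, -1] = vn[:, -2]
        wn[:, :, 0] = 0.0
        wn[:, :, -1] = 0.0

        div = (np.diff(un, axis=0) + np.diff(vn, axis=1) + np.diff(wn, axis=2)) / h
        phi = poisson.solve(rho / dt * div)
        if periodic:
            un[:-1] -= coef * (phi - np.roll(phi, 1, axis=0))
            un[-1] = un[0]
        else:
            un[1:-1] -= coef * np.diff(phi, axis=0)
        vn[:, 1:-1] -= coef * np.diff(phi, axis=1)
        vn[:, -1] += coef * 2.0 * phi[:, -1]
        wn[:, :, 1:-1] -= coef * np.diff(phi, axis=2)
        p += phi

        vscale = max(np.abs(un).max(), np.abs(vn).max(), np.abs(wn).max())
        if not np.isfinite(vscale):
            report = ConvergenceReport(False, step, dt, np.inf, history,
                                       "non-finite velocity encountered")
            raise NonConvergenceError(report.message, report)
        if vscale == 0.0:
            resid = 0.0
        else:
            resid = max(np.abs(un - u).max(), np.abs(vn - v).max(),
                        np.abs(wn - w).max()) / vscale
        u, v, w = un, vn, wn

        if step == 1 or step % settings.history_every == 0:
            history.append((step, resid))
        below = below + 1 if resid < settings.tol else 0
        if below >= settings.window:
            report = ConvergenceReport(True, step, dt, resid, history, "converged")
            break
    else:
        report = ConvergenceReport(False, settings.max_steps, dt, resid, history,
                                   "maximum pseudo-time steps reached")
        raise NonConvergenceError(report.message, report)

    v_ref = max(bc.v_ref, float(np.abs(prof).max()), 1e-300)
    return FlowField(u, v, w, p, grid, v_ref=v_ref), report


def check_divergence(field: FlowField, v_ref: float | None = None) -> float:
    """Dimensionless incompressibility diagnostic.

    Returns ``max |div u| * h / v_ref`` over all cells, with ``v_ref``
    defaulting to the field's stored reference velocity (the inlet peak
    gamma_w * H / 4).  Exactly zero for any uniform translation field.
    """
    vref = field.v_ref if v_ref is None else v_ref
    if vref <= 0:
        vref = 1.0
    return float(np.abs(field.divergence()).max() * field.grid.h / vref)
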