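"""Steady coupled free-flow / porous-biofilm momentum solver.

Finite-volume discretization on a staggered (MAC) rectilinear grid:
u on vertical faces, w (called v) on horizontal faces, pressure at cell
centres.  In the free region the momentum balance uses the total
kinematic viscosity nu + nu_t (constant eddy viscosity closure); inside
the biofilm a Brinkman balance applies, with Darcy drag (nu/K) u and the
effective viscous term scaled by 1/porosity.  Velocity and viscous
stress are continuous across the fluid-biofilm interface by
construction of the face-based fluxes.

Boundary conditions: Dirichlet velocity profile at the inlet (or zero
streamwise gradient for body-force-driven oracle configurations), zero
static pressure at the outlet, no-slip (or slip) at the bottom, slip at
the top (zero shear, zero normal velocity).

Momentum advection, when enabled, is Picard-linearized with first-order
upwinding and under-relaxation; the linear Stokes-Brinkman mode solves
one sparse system directly, satisfying discrete continuity to machine
precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ..types import ModelParams
from .domain import ModelDomain


class FlowConvergenceError(RuntimeError):
    """Picard iteration failed to converge; carries the residual history."""

    def __init__(self, message: str, history: list[float]):
        super().__init__(message)
        self.history = history


@dataclass
class FlowField:
    """Converged velocity/pressure fields on the staggered grid.

    u: (nx+1, nz) streamwise velocity at vertical faces (m/s);
    v: (nx, nz+1) vertical velocity at horizontal faces (m/s);
    p: (nx, nz) static pressure at cell centres (Pa).
    """

    u: np.ndarray
    v: np.ndarray
    p: np.ndarray
    converged: bool
    residuals: list[float] = field(default_factory=list)

    def cell_velocity(self) -> tuple[np.ndarray, np.ndarray]:
        """Velocity components interpolated to cell centres."""
        uc = 0.5 * (self.u[:-1, :] + self.u[1:, :])
        vc = 0.5 * (self.v[:, :-1] + self.v[:, 1:])
        return uc, vc

    def speed(self) -> np.ndarray:
        uc, vc = self.cell_velocity()
        return np.hypot(uc, vc)


def _effective_viscosity(domain: ModelDomain, params: ModelParams) -> np.ndarray:
    """Cell-centred kinematic effective viscosity.

    Free region: nu + nu_t; biofilm: nu / porosity (Brinkman effective
    term).  Turbulence does not penetrate the porous matrix.
    """
    nu_eff = np.full((domain.nx, domain.nz), params.nu_m2s + params.eddy_visc_m2s)
    nu_eff[domain.bio] = params.nu_m2s / params.porosity
    return nu_eff


def _darcy_drag(domain: ModelDomain, params: ModelParams) -> np.ndarray:
    """Cell-centred Darcy drag coefficient nu/K (1/s), zero in free flow."""
    drag = np.zeros((domain.nx, domain.nz))
    drag[domain.bio] = params.nu_m2s / params.permeability_m2
    return drag


def _wall_coeffs(s0: float, s1: float) -> tuple[float, float]:
    """Quadratic one-sided derivative at a wall through (0,0),(s0,u0),(s1,u1).

    Returns (A, B) with du/ds(0) = A*u0 + B*u1; exact for parabolic
    profiles, which makes the Poiseuille oracle sharp.
    """
    A = s1 / (s0 * (s1 - s0))
    B = -s0 / (s1 * (s1 - s0))
    return A, B


def _assemble(
    domain: ModelDomain,
    params: ModelParams,
    inlet_u: np.ndarray,
    bottom: str,
    inlet: str,
    body_force_x: float,
    inlet_pressure_kin: float,
    ustar: np.ndarray | None,
    vstar: np.ndarray | None,
) -> tuple[sp.csr_matrix, np.ndarray]:
    nx, nz = domain.nx, domain.nz
    dx, dz = domain.dx, domain.dz
    xc, zc = domain.xc, domain.zc
    xf, zf = domain.xf, domain.zf
    nu_c = _effective_viscosity(domain, params)
    drag_c = _darcy_drag(domain, params)
    bio = domain.bio.astype(float)

    Nu = (nx + 1) * nz
    Nv = nx * (nz + 1)
    Np = nx * nz
    N = Nu + Nv + Np
    rhs = np.zeros(N)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []

    def add(r: np.ndarray, c: np.ndarray, v: np.ndarray) -> None:
        rows.append(np.asarray(r, dtype=np.int64))
        cols.append(np.asarray(c, dtype=np.int64))
        vals.append(np.asarray(v, dtype=float))

    def iu(i: int) -> np.ndarray:
        return i * nz + np.arange(nz)

    def iv(i: int) -> np.ndarray:
        return Nu + i * (nz + 1) + np.arange(nz + 1)

    def ip(i: int) -> np.ndarray:
        return Nu + Nv + i * nz + np.arange(nz)

    advect = ustar is not None

    # ---- inlet u rows --------------------------------------------------
    if inlet == "dirichlet":
        add(iu(0), iu(0), np.ones(nz))
        rhs[iu(0)] = inlet_u
    elif inlet == "pressure":
        # momentum on the half control volume at the inlet face, with the
        # face pressure prescribed and zero upstream velocity gradient
        r = iu(0)
        dxu0 = xc[0] - xf[0]
        diag = np.zeros(nz)
        aE = nu_c[0, :] / dx[0] / dxu0
        add(r, iu(1), -aE)
        diag += aE
        nu_line = nu_c[0, :]
        corn = np.empty(nz + 1)
        corn[1:nz] = 0.5 * (nu_line[:-1] + nu_line[1:])
        corn[0] = nu_line[0]
        corn[nz] = nu_line[-1]
        aN = corn[1:nz] / (zc[1:] - zc[:-1]) / dz[:-1]
        add(r[:-1], iu(0)[1:], -aN)
        diag[:-1] += aN
        aS = corn[1:nz] / (zc[1:] - zc[:-1]) / dz[1:]
        add(r[1:], iu(0)[:-1], -aS)
        diag[1:] += aS
        if bottom == "noslip":
            A, B = _wall_coeffs(zc[0], zc[1])
            diag[0] += corn[0] * A / dz[0]
            add(r[:1], iu(0)[1:2], np.array([corn[0] * B / dz[0]]))
        diag += drag_c[0, :]
        add(r, ip(0), np.full(nz, 1.0 / dxu0))
        rhs[r] += inlet_pressure_kin / dxu0 + body_force_x
        if ustar is not None:
            me = 0.5 * (ustar[0, :] + ustar[1, :])
            mw = ustar[0, :]
            mn = vstar[0, 1:]
            ms = vstar[0, :-1]
            div = (me - mw) / dxu0 + (mn - ms) / dz
            diag -= div
            diag += np.where(me >= 0, me, 0.0) / dxu0
            add(r, iu(1), np.where(me < 0, me, 0.0) / dxu0)
            diag += -mw / dxu0  # upstream donor is u[0] either way
            diag[:-1] += np.where(mn[:-1] >= 0, mn[:-1], 0.0) / dz[:-1]
            add(r[:-1], iu(0)[1:], np.where(mn[:-1] < 0, mn[:-1], 0.0) / dz[:-1])
            diag[-1] += mn[-1] / dz[-1]
            add(r[1:], iu(0)[:-1], -np.where(ms[1:] >= 0, ms[1:], 0.0) / dz[1:])
            diag[1:] += -np.where(ms[1:] < 0, ms[1:], 0.0) / dz[1:]
        add(r, r, diag)
    else:
        raise ValueError("inlet must be 'dirichlet' or 'pressure'")

    # ---- u momentum rows (i = 1..nx) ----------------------------------
    for i in range(1, nx + 1):
        inner = i < nx
        dxu = (xc[i] - xc[i - 1]) if inner else (xf[nx] - xc[nx - 1])
        r = iu(i)
        diag = np.zeros(nz)

        iR = min(i, nx - 1)
        if inner:
            aE = nu_c[i, :] / dx[i] / dxu
            add(r, iu(i + 1), -aE)
            diag += aE
        aW = nu_c[i - 1, :] / dx[i - 1] / dxu
        add(r, iu(i - 1), -aW)
        diag += aW

        # corner viscosities on the horizontal faces of the u control volume
        nu_line = 0.5 * (nu_c[i - 1, :] + nu_c[iR, :])
        corn = np.empty(nz + 1)
        corn[1:nz] = 0.5 * (nu_line[:-1] + nu_line[1:])
        corn[0] = nu_line[0]
        corn[nz] = nu_line[-1]

        aN = corn[1:nz] / (zc[1:] - zc[:-1]) / dz[:-1]  # len nz-1
        add(r[:-1], iu(i)[1:], -aN)
        diag[:-1] += aN
        aS = corn[1:nz] / (zc[1:] - zc[:-1]) / dz[1:]
        add(r[1:], iu(i)[:-1], -aS)
        diag[1:] += aS
        # top (k = nz-1): slip, zero shear -> no flux term
        if bottom == "noslip":
            A, B = _wall_coeffs(zc[0], zc[1])
            diag[0] += corn[0] * A / dz[0]
            add(r[:1], iu(i)[1:2], np.array([corn[0] * B / dz[0]]))
        elif bottom != "slip":
            raise ValueError("bottom must be 'noslip' or 'slip'")

        diag += 0.5 * (drag_c[i - 1, :] + drag_c[iR, :]) * (
            0.5 * (bio[i - 1, :] + bio[iR, :]) > 0
        )

        cP = np.full(nz, 1.0 / dxu)
        if inner:
            add(r, ip(i), cP)
            add(r, ip(i - 1), -cP)
        else:
            add(r, ip(nx - 1), -cP)  # outlet face pressure fixed to zero

        rhs[r] += body_force_x

        if advect:
            me = 0.5 * (ustar[i, :] + ustar[i + 1, :]) if inner else ustar[nx, :]
            mw = 0.5 * (ustar[i - 1, :] + ustar[i, :])
            mn = 0.5 * (vstar[i - 1, 1:] + vstar[iR, 1:])
            ms = 0.5 * (vstar[i - 1, :-1] + vstar[iR, :-1])
            div = (me - mw) / dxu + (mn - ms) / dz
            diag -= div
            if inner:
                diag += np.where(me >= 0, me, 0.0) / dxu
                add(r, iu(i + 1), np.where(me < 0, me, 0.0) / dxu)
            else:
                diag += me / dxu
            add(r, iu(i - 1), -np.where(mw >= 0, mw, 0.0) / dxu)
            diag += -np.where(mw < 0, mw, 0.0) / dxu
            cn_int = np.where(mn[:-1] < 0, mn[:-1], 0.0) / dz[:-1]
            diag[:-1] += np.where(mn[:-1] >= 0, mn[:-1], 0.0) / dz[:-1]
            diag[-1] += mn[-1] / dz[-1]  # slip ghost: donor equals u_P
            add(r[:-1], iu(i)[1:], cn_int)
            add(r[1:], iu(i)[:-1], -np.where(ms[1:] >= 0, ms[1:], 0.0) / dz[1:])
            diag[1:] += -np.where(ms[1:] < 0, ms[1:], 0.0) / dz[1:]

        add(r, r, diag)

    # ---- v rows --------------------------------------------------------
    for i in range(nx):
        r_all = iv(i)
        # no-penetration at bottom and top
        add(r_all[[0, nz]], r_all[[0, nz]], np.ones(2))

        kk = np.arange(1, nz)
        r = r_all[kk]
        dzv = zc[kk] - zc[kk - 1]
        diag = np.zeros(nz - 1)

        aN = nu_c[i, kk] / dz[kk] / dzv
        add(r, r_all[kk + 1], -aN)
        diag += aN
        aS = nu_c[i, kk - 1] / dz[kk - 1] / dzv
        add(r, r_all[kk - 1], -aS)
        diag += aS

        iL = max(i - 1, 0)
        iR = min(i + 1, nx - 1)
        corn_w = 0.25 * (
            nu_c[iL, kk - 1] + nu_c[iL, kk] + nu_c[i, kk - 1] + nu_c[i, kk]
        )
        corn_e = 0.25 * (
            nu_c[i, kk - 1] + nu_c[i, kk] + nu_c[iR, kk - 1] + nu_c[iR, kk]
        )
        if i < nx - 1:
            aE = corn_e / (xc[i + 1] - xc[i]) / dx[i]
            add(r, iv(i + 1)[kk], -aE)
            diag += aE
        # else: outlet, zero streamwise gradient of v
        if i > 0:
            aW = corn_w / (xc[i] - xc[i - 1]) / dx[i]
            add(r, iv(i - 1)[kk], -aW)
            diag += aW
        else:
            diag += corn_w / (xc[0] - xf[0]) / dx[0]  # v = 0 on the inlet plane

        diag += 0.5 * (drag_c[i, kk - 1] + drag_c[i, kk])

        cP = 1.0 / dzv
        add(r, ip(i)[kk], cP)
        add(r, ip(i)[kk - 1], -cP)

        if advect:
            mn = 0.5 * (vstar[i, kk] + vstar[i, kk + 1])
            ms = 0.5 * (vstar[i, kk - 1] + vstar[i, kk])
            me = 0.5 * (ustar[i + 1, kk - 1] + ustar[i + 1, kk])
            mw = 0.5 * (ustar[i, kk - 1] + ustar[i, kk])
            div = (me - mw) / dx[i] + (mn - ms) / dzv
            diag -= div
            diag += np.where(mn >= 0, mn, 0.0) / dzv
            add(r, r_all[kk + 1], np.where(mn < 0, mn, 0.0) / dzv)
            add(r, r_all[kk - 1], -np.where(ms >= 0, ms, 0.0) / dzv)
            diag += -np.where(ms < 0, ms, 0.0) / dzv
            if i < nx - 1:
                diag += np.where(me >= 0, me, 0.0) / dx[i]
                add(r, iv(i + 1)[kk], np.where(me < 0, me, 0.0) / dx[i])
            else:
                diag += me / dx[i]
            if i > 0:
                add(r, iv(i - 1)[kk], -np.where(mw >= 0, mw, 0.0) / dx[i])
                diag += -np.where(mw < 0, mw, 0.0) / dx[i]
            else:
                diag += -np.where(mw < 0, mw, 0.0) / dx[i]  # inlet wall value 0

        add(r, r, diag)

    # ---- continuity rows ----------------------------------------------
    for i in range(nx):
        r = ip(i)
        add(r, iu(i + 1), np.full(nz, 1.0) / dx[i])
        add(r, iu(i), -np.full(nz, 1.0) / dx[i])
        add(r, iv(i)[1:], 1.0 / dz)
        add(r, iv(i)[:-1], -1.0 / dz)

    mat = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(N, N),
    ).tocsr()
    return mat, rhs


def solve_flow(
    domain: ModelDomain,
    params: ModelParams,
    inlet_profile: Callable[[np.ndarray], np.ndarray] | np.ndarray | None = None,
    *,
    bottom: str = "noslip",
    inlet: str = "dirichlet",
    body_force_x: float = 0.0,
    inlet_pressure_pa: float = 0.0,
    advection: bool = True,
    max_picard: int = 60,
    tol: float = 1e-6,
    relax: float = 0.7,
) -> FlowField:
    """Solve the steady coupled momentum/continuity problem.

    inlet_profile: callable u(z) or array of u at cell-centre heights
    (m/s); None means zero.  With inlet="pressure" the inlet static
    pressure is prescribed (Pa, relative to the zero outlet pressure)
    and the velocity there follows from momentum -- the configuration of
    the pressure-driven channel and Darcy-slab oracles.  body_force_x is
    a kinematic streamwise force (m/s^2).  Raises FlowConvergenceError
    if the Picard loop does not reach the relative tolerance within
    max_picard iterations.
    """
    nx, nz = domain.nx, domain.nz
    if inlet_profile is None:
        inlet_u = np.zeros(nz)
    elif callable(inlet_profile):
        inlet_u = np.asarray(inlet_profile(domain.zc), dtype=float)
    else:
        inlet_u = np.asarray(inlet_profile, dtype=float)
        if inlet_u.shape != (nz,):
            raise ValueError("inlet profile array must have one value per z cell")

    def unpack(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        Nu = (nx + 1) * nz
        Nv = nx * (nz + 1)
        u = x[:Nu].reshape(nx + 1, nz)
        v = x[Nu : Nu + Nv].reshape(nx, nz + 1)
        p = x[Nu + Nv :].reshape(nx, nz) * params.rho_kgm3
        return u, v, p

    p_in_kin = inlet_pressure_pa / params.rho_kgm3

    # linear Stokes-Brinkman solve (also the Picard starting point)
    mat, rhs = _assemble(
        domain, params, inlet_u, bottom, inlet, body_force_x, p_in_kin, None, None
    )
    x = spla.spsolve(mat, rhs)
    u, v, p = unpack(x)
    if not advection:
        return FlowField(u=u, v=v, p=p, converged=True, residuals=[0.0])

    history: list[float] = []
    scale = max(np.abs(u).max(), np.abs(inlet_u).max(), 1e-30)
    for _ in range(max_picard):
        mat, rhs = _assemble(
            domain, params, inlet_u, bottom, inlet, body_force_x, p_in_kin, u, v
        )
        x = spla.spsolve(mat, rhs)
        u_new, v_new, p_new = unpack(x)
        change = max(
            np.abs(u_new - u).max() / scale,
            np.abs(v_new - v).max() / scale,
        )
        history.append(float(change))
        u = relax * u_new + (1 - relax) * u
        v = relax * v_new + (1 - relax) * v
        p = relax * p_new + (1 - relax) * p
        if change < tol:
            return FlowField(u=u, v=v, p=p, converged=True, residuals=history)
    raise FlowConvergenceError(
        f"Picard iteration did not converge below {tol:g} in {max_picard} steps "
        f"(last residual {history[-1]:.3e})",
        history,
    )


def fit_inlet_profile(points: np.ndarray) -> np.poly1d:
    """Quadratic polynomial fit of velocimetry points (z_m, u_ms, ...).

    Returns a callable u(z) used as the inlet Dirichlet profile; exact
    round trip for noise-free quadratic data.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 velocimetry points")
    return np.poly1d(np.polyfit(pts[:, 0], pts[:, 1], 2))


def mass_conservation_residual(domain: ModelDomain, flow: FlowField) -> float:
    """|inflow - outflow| relative to the inflow scale."""
    inflow = float(np.sum(flow.u[0, :] * domain.dz))
    outflow = float(np.sum(flow.u[-1, :] * domain.dz))
    scale = max(abs(inflow), abs(outflow), 1e-30)
    return abs(inflow - outflow) / scale
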