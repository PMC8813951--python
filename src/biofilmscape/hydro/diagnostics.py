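"""Post-processing of converged flow/concentration fields.

Covers the advective/diffusive flux decomposition Jc/Jd, wall-shear and
diffusive-boundary-layer scales (u* = sqrt(tau/rho), delta = nu/u*,
DBL = delta/sqrt(Sc)), and biofilm-internal velocity statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..types import ModelParams
from .domain import ModelDomain
from .flow import FlowField
from .transport import ConcField, _cell_diffusivity


@dataclass
class FluxDecomposition:
    """Per-cell ratio of advective to diffusive O2 flux magnitudes.

    ratio: |u c| / (D |grad c|) per cell, +inf where the diffusive flux
    vanishes; biofilm_mean excludes non-finite cells; the surface
    advective fraction is the advective share of the total exchange
    magnitude across the fluid-biofilm interface.
    """

    ratio: np.ndarray
    biofilm_mean: float
    biofilm_median: float
    surface_advective_fraction: float


def flux_decomposition(
    domain: ModelDomain,
    flow: FlowField,
    conc: ConcField,
    params: ModelParams,
    x_min_m: float = 0.0,
) -> FluxDecomposition:
    """Advective/diffusive flux decomposition of the O2 field.

    x_min_m excludes the inlet entrance region from the biofilm
    statistics: the imposed inlet velocity profile over-predicts flow
    inside the porous inlet cells and equilibrates within about 1 mm
    downstream.
    """
    uc, vc = flow.cell_velocity()
    c = conc.c
    dcdx = np.gradient(c, domain.xc, axis=0)
    dcdz = np.gradient(c, domain.zc, axis=1)
    grad = np.hypot(dcdx, dcdz)
    d_cell = _cell_diffusivity(domain, params)

    speed = np.hypot(uc, vc)
    adv = speed * np.abs(c)
    diff = d_cell * grad
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(diff > 0, adv / diff, np.inf)

    in_bio = domain.bio & np.isfinite(ratio) & (domain.xc[:, None] >= x_min_m)
    biofilm_mean = float(ratio[in_bio].mean()) if in_bio.any() else float("nan")
    biofilm_median = float(np.median(ratio[in_bio])) if in_bio.any() else float("nan")

    # exchange across the fluid-biofilm interface
    adv_sum = 0.0
    diff_sum = 0.0
    nx, nz = domain.nx, domain.nz
    bio = domain.bio
    # vertical faces between biofilm and free cells
    for i in range(nx - 1):
        mask = bio[i, :] != bio[i + 1, :]
        if not mask.any():
            continue
        cf = 0.5 * (c[i, mask] + c[i + 1, mask])
        uf = flow.u[i + 1, mask]
        dist = domain.xc[i + 1] - domain.xc[i]
        dface = 2.0 / (1.0 / d_cell[i, mask] + 1.0 / d_cell[i + 1, mask])
        adv_sum += float(np.sum(np.abs(uf * cf) * domain.dz[mask]))
        diff_sum += float(
            np.sum(np.abs(dface * (c[i + 1, mask] - c[i, mask]) / dist) * domain.dz[mask])
        )
    # horizontal faces between biofilm and free cells (biofilm top)
    for k in range(nz - 1):
        mask = bio[:, k] != bio[:, k + 1]
        if not mask.any():
            continue
        cf = 0.5 * (c[mask, k] + c[mask, k + 1])
        vf = flow.v[mask, k + 1]
        dist = domain.zc[k + 1] - domain.zc[k]
        dface = 2.0 / (1.0 / d_cell[mask, k] + 1.0 / d_cell[mask, k + 1])
        adv_sum += float(np.sum(np.abs(vf * cf) * domain.dx[mask]))
        diff_sum += float(
            np.sum(np.abs(dface * (c[mask, k + 1] - c[mask, k]) / dist) * domain.dx[mask])
        )
    total = adv_sum + diff_sum
    frac = adv_sum / total if total > 0 else float("nan")
    return FluxDecomposition(
        ratio=ratio,
        biofilm_mean=biofilm_mean,
        biofilm_median=biofilm_median,
        surface_advective_fraction=frac,
    )


def _column_wall_shear(
    domain: ModelDomain, flow: FlowField, params: ModelParams
) -> np.ndarray:
    """Wall shear stress (Pa) per column, evaluated just above the local
    biofilm surface (or the bottom wall where there is no biofilm)."""
    uc, _ = flow.cell_velocity()
    mu_eff = params.rho_kgm3 * (params.nu_m2s + params.eddy_visc_m2s)
    tau = np.zeros(domain.nx)
    for i in range(domain.nx):
        h = domain.elevation_m[i]
        above = np.flatnonzero(domain.zc > h)
        if above.size < 2:
            tau[i] = 0.0
            continue
        k0, k1 = above[0], above[1]
        s0, s1 = domain.zc[k0] - h, domain.zc[k1] - h
        # quadratic-exact one-sided derivative through the surface
        u_surf = 0.0 if h == 0.0 else float(uc[i, np.flatnonzero(domain.zc <= h)[-1]])
        dudz = (
            (uc[i, k0] - u_surf) * s1**2 - (uc[i, k1] - u_surf) * s0**2
        ) / (s0 * s1 * (s1 - s0))
        tau[i] = mu_eff * dudz
    return tau


def wall_shear_dbl(
    domain: ModelDomain, flow: FlowField, params: ModelParams
) -> dict[str, float]:
    """Average wall shear over the biofilm surface and derived scales.

    Returns tau (Pa), u_star (m/s), delta = nu/u_star (m) and
    DBL_scale = delta/sqrt(Sc) (m) with Sc = nu/D_aq.  Zero shear is
    reported as infinite delta (flagged via the 'degenerate' key).
    """
    tau_cols = _column_wall_shear(domain, flow, params)
    tau = float(np.mean(np.abs(tau_cols)))
    if tau <= 0.0:
        return {
            "tau_pa": 0.0,
            "u_star_ms": 0.0,
            "delta_m": float("inf"),
            "dbl_scale_m": float("inf"),
            "degenerate": True,
        }
    u_star = float(np.sqrt(tau / params.rho_kgm3))
    delta = params.nu_m2s / u_star
    sc = params.nu_m2s / params.d_aq_m2s
    return {
        "tau_pa": tau,
        "u_star_ms": u_star,
        "delta_m": delta,
        "dbl_scale_m": delta / np.sqrt(sc),
        "degenerate": False,
    }


def internal_velocity_stats(
    domain: ModelDomain, flow: FlowField, params: ModelParams | None = None
) -> dict[str, object]:
    """Biofilm-internal mean speed and viscous-sublayer thickness profile.

    The sublayer thickness per column is the height above the surface up
    to which u(z) follows the linear wall scaling u = (tau/mu)(z - h)
    within 10%.
    """
    speed = flow.speed()
    vol = domain.cell_volumes()
    in_bio = domain.bio
    if in_bio.any():
        mean_speed = float(np.sum(speed[in_bio] * vol[in_bio]) / np.sum(vol[in_bio]))
    else:
        mean_speed = 0.0

    sublayer = np.full(domain.nx, np.nan)
    if params is not None:
        uc, _ = flow.cell_velocity()
        tau_cols = _column_wall_shear(domain, flow, params)
        mu_eff = params.rho_kgm3 * (params.nu_m2s + params.eddy_visc_m2s)
        for i in range(domain.nx):
            if tau_cols[i] == 0.0:
                continue
            h = domain.elevation_m[i]
            above = np.flatnonzero(domain.zc > h)
            thick = 0.0
            for k in above:
                z_rel = domain.zc[k] - h
                u_lin = tau_cols[i] / mu_eff * z_rel
                if u_lin == 0.0 or abs(uc[i, k] - u_lin) > 0.1 * abs(u_lin):
                    break
                thick = z_rel
            sublayer[i] = thick
    return {"mean_speed_ms": mean_speed, "sublayer_thickness_m": sublayer}
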