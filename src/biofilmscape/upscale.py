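"""Patch-to-landscape upscaling of metabolic rates, plus flume hydraulics.

Volumetric rates (mmol O2 m^-3 s^-1; respiration negative) measured or
fitted per patch type are converted to areal fluxes across the projected
planar area by multiplying with the mean patch thickness, carried in mm
to match the survey's printed convention (the printed unit label
mmol m^-2 s^-1 is reproduced as-is; see the methods note for the unit
caveat).  Landscape aggregates are volume-weighted: the landscape
volumetric rate is sum(vol_i * rate_i) / sum(vol_i) and the landscape
areal flux is that rate times sum(vol)/sum(area).  Spatial arrangement
of patches is deliberately ignored.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .types import LandscapeBudget, PatchBudget


def mean_velocity(discharge_m3s: float, depth_m: float, width_m: float) -> float:
    """Cross-section-averaged flow velocity u = Q / (h * w)."""
    if depth_m <= 0 or width_m <= 0:
        raise ValueError("depth and width must be positive")
    return discharge_m3s / (depth_m * width_m)


def tke(u_rms: float, v_rms: float, w_rms: float) -> float:
    """Turbulent kinetic energy from RMS velocity fluctuations,
    TKE = (u'^2 + v'^2 + w'^2) / 2."""
    return 0.5 * (u_rms**2 + v_rms**2 + w_rms**2)


def patch_areal_flux(rate_vol: float, volume_mm3: float, area_mm2: float) -> float:
    """Areal flux = volumetric rate x mean thickness (volume/area, mm)."""
    if area_mm2 <= 0:
        raise ValueError("patch area must be positive")
    return rate_vol * (volume_mm3 / area_mm2)


def landscape_budget(patches: Iterable[PatchBudget]) -> LandscapeBudget:
    """Volume-weighted aggregation of patch budgets."""
    patches = list(patches)
    total_vol = sum(p.volume_mm3 for p in patches)
    if total_vol <= 0:
        raise ValueError("total biofilm volume must be positive")
    total_area = sum(p.area_mm2 for p in patches)
    r_vol = sum(p.volume_mm3 * p.r_vol for p in patches) / total_vol
    np_vol = sum(p.volume_mm3 * p.np_vol for p in patches) / total_vol
    return LandscapeBudget(
        r_vol=r_vol,
        np_vol=np_vol,
        total_area_mm2=total_area,
        total_volume_mm3=total_vol,
    )


def budget_table(patches: Iterable[PatchBudget]) -> pd.DataFrame:
    """Patch budgets plus the landscape row as a tidy table."""
    patches = list(patches)
    rows = []
    for p in patches:
        rows.append(
            {
                "patch_type": p.patch_type,
                "R_vol": p.r_vol,
                "NP_vol": p.np_vol,
                "NEP_vol": p.nep_vol,
                "R_area": p.r_area,
                "NP_area": p.np_area,
                "NEP_area": p.nep_area,
                "area_mm2": p.area_mm2,
                "volume_mm3": p.volume_mm3,
            }
        )
    land = landscape_budget(patches)
    rows.append(
        {
            "patch_type": "landscape",
            "R_vol": land.r_vol,
            "NP_vol": land.np_vol,
            "NEP_vol": land.nep_vol,
            "R_area": land.r_area,
            "NP_area": land.np_area,
            "NEP_area": land.nep_area,
            "area_mm2": land.total_area_mm2,
            "volume_mm3": land.total_volume_mm3,
        }
    )
    return pd.DataFrame(rows)


def round_half_up(value: float, decimals: int) -> float:
    """Half-up rounding to a fixed number of decimals, matching how the
    survey tables print their values (numpy/python round half-to-even)."""
    import decimal

    q = decimal.Decimal(10) ** -decimals
    return float(
        decimal.Decimal(repr(value)).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )
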