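"""Model-domain construction for the 2D coupled water/biofilm solver.

The domain is a rectangle of fixed height (default 5 mm) spanning one
patch cross-section in the flow direction.  Cells below the (optionally
smoothed) elevation profile belong to the biofilm (porous) region; the
rest is free-flowing water.  The vertical grid is refined in a band
covering the biofilm and the fluid-biofilm interface (this also provides
the inflation layer at the bottom) and coarsens geometrically above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np


@dataclass
class GridConfig:
    """Structured-grid resolution controls (all lengths in metres)."""

    nx: int = 48
    height_m: float = 0.005
    dz_fine_m: float = 2.5e-5
    dz_max_m: float = 2.5e-4
    growth: float = 1.3
    band_m: float = 1.5e-4  # fine-band margin above the highest elevation
    smooth_sigma_mm: float = 0.0  # Gaussian smoothing of the elevation curve


def _z_faces(cfg: GridConfig, elev_max_m: float) -> np.ndarray:
    """Vertical face coordinates: fine band then geometric coarsening."""
    fine_top = min(cfg.height_m, max(elev_max_m + cfg.band_m, 3 * cfg.dz_fine_m))
    n_fine = max(3, int(np.ceil(fine_top / cfg.dz_fine_m)))
    dz = [fine_top / n_fine] * n_fine
    z = fine_top
    step = dz[-1]
    coarse: list[float] = []
    while z < cfg.height_m - 1e-12:
        step = min(step * cfg.growth, cfg.dz_max_m)
        coarse.append(step)
        z += step
    if coarse:
        # rescale the coarse tail so faces end exactly at the domain top
        factor = (cfg.height_m - fine_top) / sum(coarse)
        coarse = [c * factor for c in coarse]
    return np.concatenate([[0.0], np.cumsum(dz + coarse)])


@dataclass
class ModelDomain:
    """Discretized 2D water + biofilm domain.

    xf, zf: face coordinates (m); bio: binary biofilm indicator per cell
    (nx, nz); fill: fractional biofilm occupancy per cell, used for
    geometric accounting (areas); elevation_m: surface height at cell
    centres.
    """

    xf: np.ndarray
    zf: np.ndarray
    elevation_m: np.ndarray
    bio: np.ndarray
    fill: np.ndarray
    config: GridConfig = field(default_factory=GridConfig)

    @cached_property
    def xc(self) -> np.ndarray:
        return 0.5 * (self.xf[:-1] + self.xf[1:])

    @cached_property
    def zc(self) -> np.ndarray:
        return 0.5 * (self.zf[:-1] + self.zf[1:])

    @cached_property
    def dx(self) -> np.ndarray:
        return np.diff(self.xf)

    @cached_property
    def dz(self) -> np.ndarray:
        return np.diff(self.zf)

    @property
    def nx(self) -> int:
        return self.xf.size - 1

    @property
    def nz(self) -> int:
        return self.zf.size - 1

    @property
    def cell_count(self) -> int:
        return self.nx * self.nz

    @property
    def width_m(self) -> float:
        return float(self.xf[-1] - self.xf[0])

    @property
    def height_m(self) -> float:
        return float(self.zf[-1] - self.zf[0])

    def biofilm_area_m2(self) -> float:
        """Cross-sectional biofilm area from fractional cell occupancy."""
        return float(np.sum(self.fill * self.dx[:, None] * self.dz[None, :]))

    def cell_volumes(self) -> np.ndarray:
        """Per-cell area (m^2); the 2D model is per unit span."""
        return self.dx[:, None] * self.dz[None, :]


def build_domain(
    elevation_mm: np.ndarray,
    width_mm: float,
    config: GridConfig | None = None,
) -> ModelDomain:
    """Build a ModelDomain from a 1D elevation profile.

    elevation_mm: biofilm surface heights (mm) sampled uniformly along the
    flow direction over [0, width_mm].  Heights exceeding the domain
    height are clipped with a warning.
    """
    cfg = config or GridConfig()
    elev = np.asarray(elevation_mm, dtype=float) * 1e-3
    if elev.ndim != 1 or elev.size < 2:
        raise ValueError("elevation profile must be a 1D array of >= 2 samples")
    if not np.all(np.isfinite(elev)):
        raise ValueError("elevation profile must be finite")
    if np.any(elev < 0):
        raise ValueError("elevation profile must be non-negative")
    width_m = width_mm * 1e-3
    if width_m <= 0:
        raise ValueError("width must be positive")

    xf = np.linspace(0.0, width_m, cfg.nx + 1)
    xc = 0.5 * (xf[:-1] + xf[1:])
    x_in = np.linspace(0.0, width_m, elev.size)
    elev_c = np.interp(xc, x_in, elev)

    if cfg.smooth_sigma_mm > 0:
        from scipy.ndimage import gaussian_filter1d

        sigma_px = cfg.smooth_sigma_mm * 1e-3 / (width_m / cfg.nx)
        elev_c = gaussian_filter1d(elev_c, sigma_px, mode="nearest")

    if np.any(elev_c > cfg.height_m):
        warnings.warn(
            "elevation exceeds domain height; clipping to the domain top",
            stacklevel=2,
        )
        elev_c = np.minimum(elev_c, cfg.height_m)

    zf = _z_faces(cfg, float(elev_c.max()))
    zc = 0.5 * (zf[:-1] + zf[1:])
    dz = np.diff(zf)

    bio = zc[None, :] < elev_c[:, None]
    fill = np.clip((elev_c[:, None] - zf[None, :-1]) / dz[None, :], 0.0, 1.0)
    return ModelDomain(xf=xf, zf=zf, elevation_m=elev_c, bio=bio, fill=fill, config=cfg)
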