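"""Shared data containers for the biofilm landscape pipeline.

Rasters are row-major with axis order (y, x) for maps and (z, y, x) for
volumes; origin at the upstream-left corner; heights in mm above the
substrate plane; pixel extents carried as metadata (half-open intervals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

# Patch-type label codes used in every PatchLabelMap raster.
BACKGROUND = 0
CDB = 1  # cyanobacteria-dominated base layer
DDP = 2  # diatom-dominated patches
KDP = 3  # Klebsormidiophyceae-dominated patches

PATCH_NAMES = {CDB: "CDB", DDP: "DDP", KDP: "KDP", BACKGROUND: "background"}
PATCH_CODES = {v: k for k, v in PATCH_NAMES.items()}


@dataclass
class ElevationMap:
    """Digital elevation model of the biofilm surface.

    heights: 2D raster (mm above the substrate plane), shape (ny, nx).
    pixel_mm: raster resolution in mm per pixel (isotropic in x-y).
    origin_mm: (x, y) offset of pixel (0, 0) in mm.
    """

    heights: np.ndarray
    pixel_mm: float
    origin_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2D raster")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must be finite")
        if np.any(self.heights < 0):
            raise ValueError("heights must be non-negative")
        if self.pixel_mm <= 0:
            raise ValueError("pixel_mm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_mm**2


@dataclass
class PatchLabelMap:
    """Raster assigning each pixel to a patch type (or background)."""

    labels: np.ndarray
    pixel_mm: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2D raster")
        valid = {BACKGROUND, CDB, DDP, KDP}
        if not set(np.unique(self.labels)).issubset(valid):
            raise ValueError("labels must be in {background, CDB, DDP, KDP}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def mask(self, code: int) -> np.ndarray:
        return self.labels == code


@dataclass
class PatchParams:
    """Per-patch-type generator targets."""

    mean_height_mm: float
    sd_height_mm: float
    target_coverage_fraction: float
    target_porosity: float

    def __post_init__(self) -> None:
        if self.mean_height_mm < 0 or self.sd_height_mm < 0:
            raise ValueError("heights must be non-negative")
        if not 0.0 <= self.target_coverage_fraction <= 1.0:
            raise ValueError("coverage fraction must be in [0, 1]")
        if not 0.0 <= self.target_porosity <= 1.0:
            raise ValueError("porosity must be in [0, 1]")


@dataclass
class LandscapeSpec:
    """Targets for the synthetic biofilm landscape generator.

    patch_params maps label codes (CDB, DDP, KDP) to PatchParams.  DDP and
    KDP coverages are honoured explicitly; CDB fills the remainder.
    """

    domain_size_mm: tuple[float, float]
    pixel_mm: float
    patch_params: dict[int, PatchParams]
    seed: int = 0
    blob_smooth_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.pixel_mm <= 0:
            raise ValueError("pixel_mm must be positive")
        if any(s <= 0 for s in self.domain_size_mm):
            raise ValueError("domain size must be positive")
        cov = sum(
            p.target_coverage_fraction
            for code, p in self.patch_params.items()
            if code != CDB
        )
        if cov > 1.0 + 1e-12:
            raise ValueError("non-CDB coverage fractions must sum to <= 1")

    @property
    def raster_shape(self) -> tuple[int, int]:
        nx = int(round(self.domain_size_mm[0] / self.pixel_mm))
        ny = int(round(self.domain_size_mm[1] / self.pixel_mm))
        return (ny, nx)


@dataclass
class SensorNoiseSpec:
    """Microsensor sampling and noise model."""

    sigma_conc: float = 0.0  # mol m^-3
    vertical_step_mm: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_conc < 0:
            raise ValueError("sigma_conc must be >= 0")
        if self.vertical_step_mm <= 0:
            raise ValueError("vertical_step_mm must be positive")


@dataclass
class Profile:
    """One vertical O2 profile: z increasing upward from the substrate."""

    x_mm: float
    z_mm: np.ndarray
    conc: np.ndarray  # mol m^-3
    surface_z_mm: float | None = None

    def __post_init__(self) -> None:
        self.z_mm = np.asarray(self.z_mm, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.z_mm.shape != self.conc.shape:
            raise ValueError("z and concentration arrays must align")
        if self.z_mm.size >= 2 and not np.all(np.diff(self.z_mm) > 0):
            raise ValueError("z must be strictly increasing within a profile")


@dataclass
class MicroprofileTransect:
    """Ordered set of vertical O2 profiles along the flow direction."""

    profiles: list[Profile]
    light: bool
    flow: str = "slow"
    patch_type: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.profiles = sorted(self.profiles, key=lambda p: p.x_mm)

    def points(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All samples as flat (x_mm, z_mm, conc) arrays."""
        xs, zs, cs = [], [], []
        for p in self.profiles:
            xs.append(np.full(p.z_mm.size, p.x_mm))
            zs.append(p.z_mm)
            cs.append(p.conc)
        if not xs:
            return (np.empty(0),) * 3
        return np.concatenate(xs), np.concatenate(zs), np.concatenate(cs)


@dataclass
class ModelParams:
    """Physical parameters of the coupled flow/transport model.

    Units: permeability m^2; viscosities/diffusivities m^2 s^-1;
    rate mol m^-3 s^-1 (negative = consumption/respiration, positive =
    net photosynthesis); density kg m^-3.
    """

    porosity: float = 0.5
    permeability_m2: float = 1e-10
    c_eff_diff: float = 0.7  # D_eff / D_aq inside the biofilm
    prandtl_t: float = 1.0
    eddy_visc_m2s: float = 1e-5
    rate_mol_m3s: float = 0.0
    d_aq_m2s: float = 1.67e-9  # O2 in water at 15 C
    nu_m2s: float = 1.139e-6  # kinematic viscosity at 15 C
    rho_kgm3: float = 999.1

    def __post_init__(self) -> None:
        if not 0.0 < self.porosity <= 1.0:
            raise ValueError("porosity must be in (0, 1]")
        if self.permeability_m2 <= 0:
            raise ValueError("permeability must be positive")
        if not 0.0 < self.c_eff_diff <= 1.0:
            raise ValueError("effective diffusivity ratio must be in (0, 1]")
        if self.prandtl_t <= 0:
            raise ValueError("turbulent Prandtl number must be positive")
        if self.eddy_visc_m2s < 0:
            raise ValueError("eddy viscosity must be >= 0")

    @property
    def eddy_diff_m2s(self) -> float:
        """Eddy diffusivity D_t = nu_t / Pr_t (holds by construction)."""
        return self.eddy_visc_m2s / self.prandtl_t

    @property
    def d_eff_m2s(self) -> float:
        return self.c_eff_diff * self.d_aq_m2s

    def replace(self, **kwargs) -> "ModelParams":
        from dataclasses import replace

        return replace(self, **kwargs)


@dataclass
class HydraulicSummary:
    """Bulk flume hydraulics: mean velocity and turbulence intensity."""

    discharge_m3s: float
    depth_m: float
    width_m: float
    u_rms_ms: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def mean_velocity_ms(self) -> float:
        from .upscale import mean_velocity

        return mean_velocity(self.discharge_m3s, self.depth_m, self.width_m)

    @property
    def tke_m2s2(self) -> float:
        from .upscale import tke

        return tke(*self.u_rms_ms)


@dataclass
class PatchBudget:
    """Volumetric metabolic rates and areal O2 fluxes for one patch type.

    Volumetric rates in mmol m^-3 s^-1 (R negative); areal fluxes carry
    the survey's printed unit (mmol m^-2 s^-1) and are computed as
    volumetric rate x mean thickness in mm.
    """

    patch_type: str
    r_vol: float
    np_vol: float
    area_mm2: float
    volume_mm3: float

    @property
    def nep_vol(self) -> float:
        return self.np_vol + self.r_vol

    @property
    def thickness_mm(self) -> float:
        if self.area_mm2 <= 0:
            raise ValueError("patch area must be positive")
        return self.volume_mm3 / self.area_mm2

    @property
    def r_area(self) -> float:
        return self.r_vol * self.thickness_mm

    @property
    def np_area(self) -> float:
        return self.np_vol * self.thickness_mm

    @property
    def nep_area(self) -> float:
        return self.nep_vol * self.thickness_mm


@dataclass
class LandscapeBudget:
    """Volume-weighted landscape aggregate of patch budgets."""

    r_vol: float
    np_vol: float
    total_area_mm2: float
    total_volume_mm3: float

    @property
    def nep_vol(self) -> float:
        return self.np_vol + self.r_vol

    @property
    def thickness_mm(self) -> float:
        return self.total_volume_mm3 / self.total_area_mm2

    @property
    def r_area(self) -> float:
        return self.r_vol * self.thickness_mm

    @property
    def np_area(self) -> float:
        return self.np_vol * self.thickness_mm

    @property
    def nep_area(self) -> float:
        return self.nep_vol * self.thickness_mm


@dataclass
class FitSpec:
    """Configuration of the least-squares parameter search.

    free: names of ModelParams fields to optimize, a subset of
    {rate_mol_m3s, permeability_m2, porosity, c_eff_diff, prandtl_t,
    eddy_visc_m2s}.  bounds/init keyed by the same names.
    """

    free: Sequence[str]
    bounds: dict[str, tuple[float, float]]
    init: dict[str, float]
    xtol: float = 1e-4
    max_iter: int = 400
    restarts: int = 3

    def __post_init__(self) -> None:
        for name in self.free:
            lo, hi = self.bounds[name]
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name} must be finite and ordered")
            if not lo <= self.init[name] <= hi:
                raise ValueError(f"initial value for {name} outside bounds")


@dataclass
class FitResult:
    """Outcome of fit_parameters."""

    params: ModelParams
    objective: float  # sum of squared residuals, (mol m^-3)^2
    correlations: list[float]  # per-profile Pearson r, model vs data
    n_eval: int
    converged: bool
    history: list[float] = field(default_factory=list)
    restart_objectives: list[float] = field(default_factory=list)
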