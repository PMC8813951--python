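"""Synthetic biofilm landscapes and instrument-like observations.

Stands in for the flume experiment: generates patchy landscapes (a
cyanobacteria-dominated base with diatom- and Klebsormidiophyceae-
dominated blobs), OCT-like intensity volumes, RGB macrophotographs,
inlet velocimetry points, and forward-modelled O2 microsensor transects,
so that every downstream stage can be tested without measured data.

Patch blobs are Gaussian-smoothed thresholded noise fields — simple and
controllable, with no claim of biological realism.  All randomness is
drawn from one seeded generator per operation; seeds are recorded in
output metadata where applicable.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter, uniform_filter

from .types import (
    CDB,
    DDP,
    KDP,
    ElevationMap,
    LandscapeSpec,
    MicroprofileTransect,
    ModelParams,
    PatchLabelMap,
    Profile,
    SensorNoiseSpec,
)

# gray-level conventions of the OCT emulation: void < 120 <= ambiguous
# <= 130 < biomass, so the two-threshold porosity uncertainty band is
# exercised by construction
GRAY_VOID_MAX = 119
GRAY_AMBIG_LO = 120
GRAY_AMBIG_HI = 130
GRAY_BIOMASS_MIN = 131
GRAY_SUBSTRATE = 255
GRAY_BACKGROUND_MAX = 60
AMBIGUOUS_FRACTION = 0.04  # sub-surface voxels placed between thresholds

# default macrophotograph coloration (R, G, B) per patch type
_PATCH_COLORS = {
    CDB: (90.0, 110.0, 70.0),  # brownish green base
    DDP: (140.0, 90.0, 60.0),  # brown, elevated red/green ratio
    KDP: (60.0, 180.0, 70.0),  # bright green filaments
}


def _smooth_unit_field(shape, sigma_px: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian-smoothed white noise, standardized to zero mean/unit SD."""
    f = gaussian_filter(rng.standard_normal(shape), sigma_px, mode="wrap")
    sd = f.std()
    if sd == 0:
        return np.zeros(shape)
    return (f - f.mean()) / sd


def gen_landscape(spec: LandscapeSpec) -> tuple[ElevationMap, PatchLabelMap]:
    """Generate a patchy landscape hitting the spec's coverage and height
    statistics.

    DDP and KDP are placed as smoothed random blobs (KDP takes
    precedence) on a CDB base; per-type heights are standardized over
    each patch mask so realized means match the targets up to clipping
    at zero.  Deterministic for a fixed spec.seed.
    """
    shape = spec.raster_shape
    n_pix = shape[0] * shape[1]
    rng = np.random.default_rng(spec.seed)
    sigma_px = spec.blob_smooth_mm / spec.pixel_mm

    labels = np.full(shape, CDB, dtype=np.int8)
    for code in (KDP, DDP):  # KDP first: precedence over DDP
        pp = spec.patch_params.get(code)
        if pp is None or pp.target_coverage_fraction <= 0:
            continue
        n_target = pp.target_coverage_fraction * n_pix
        if n_target < 1:
            raise ValueError(
                f"coverage {pp.target_coverage_fraction} for label {code} is below "
                f"one pixel at resolution {spec.pixel_mm} mm"
            )
        blob = _smooth_unit_field(shape, sigma_px, rng)
        free = labels == CDB
        if free.sum() < n_target:
            raise ValueError("coverage fractions infeasible: no free pixels left")
        # threshold chosen on the free pixels so the realized count over the
        # whole raster matches the target coverage
        thr = np.quantile(blob[free], 1.0 - n_target / free.sum())
        labels[free & (blob > thr)] = code

    heights = np.zeros(shape)
    for code, pp in spec.patch_params.items():
        mask = labels == code
        if not mask.any():
            continue
        f = _smooth_unit_field(shape, sigma_px, rng)
        fm = f[mask]
        sd = fm.std()
        fm = (fm - fm.mean()) / sd if sd > 0 else np.zeros(fm.shape)
        heights[mask] = np.clip(pp.mean_height_mm + pp.sd_height_mm * fm, 0.0, None)

    return (
        ElevationMap(heights=heights, pixel_mm=spec.pixel_mm),
        PatchLabelMap(labels=labels, pixel_mm=spec.pixel_mm),
    )


def gen_oct_volume(
    dem: ElevationMap,
    labels: PatchLabelMap,
    spec: LandscapeSpec,
    axial_step_mm: float = 0.005,
    headroom_mm: float = 0.3,
    seed: int | None = None,
) -> np.ndarray:
    """Emulate an OCT intensity volume above a reflective substrate.

    Returns a uint8 volume of shape (nzv, ny, nx) with voxel index 0 at
    the substrate plane (gray 255).  Sub-surface voxels are biomass or
    void according to the per-type target porosity, with a small
    fraction placed between the two segmentation thresholds and a
    one-voxel biomass skin at the surface (OCT always returns signal at
    the interface); voxels above the surface carry low-intensity noise.
    """
    if dem.shape != labels.shape:
        raise ValueError("DEM and label rasters must share a shape")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    dz = axial_step_mm
    ny, nx = dem.shape
    nzv = int(np.ceil((dem.heights.max() + headroom_mm) / dz)) + 1

    vol = rng.integers(0, GRAY_BACKGROUND_MAX + 1, size=(nzv, ny, nx), dtype=np.uint8)
    vol[0, :, :] = GRAY_SUBSTRATE

    # voxel k spans [k*dz, (k+1)*dz); the surface voxel is floor(h/dz)
    ks = np.floor(dem.heights / dz).astype(int)
    kz = np.arange(nzv)[:, None, None]
    below = (kz >= 1) & (kz < ks[None, :, :])
    skin = (kz == ks[None, :, :]) & (dem.heights[None, :, :] > 0)

    p_void = np.zeros((ny, nx))
    for code, pp in spec.patch_params.items():
        # centre the two-threshold band on the target porosity
        p_void[labels.labels == code] = np.clip(
            pp.target_porosity - AMBIGUOUS_FRACTION / 2,
            0.0,
            1.0 - AMBIGUOUS_FRACTION,
        )

    draw = rng.random((nzv, ny, nx))
    is_void = below & (draw < p_void[None, :, :])
    is_ambig = below & ~is_void & (draw < p_void[None, :, :] + AMBIGUOUS_FRACTION)
    is_biomass = (below & ~is_void & ~is_ambig) | skin

    vol[is_void] = rng.integers(
        0, GRAY_VOID_MAX + 1, size=int(is_void.sum()), dtype=np.uint8
    )
    vol[is_ambig] = rng.integers(
        GRAY_AMBIG_LO, GRAY_AMBIG_HI + 1, size=int(is_ambig.sum()), dtype=np.uint8
    )
    vol[is_biomass] = rng.integers(
        GRAY_BIOMASS_MIN, 251, size=int(is_biomass.sum()), dtype=np.uint8
    )
    return vol


def gen_macrophoto(
    dem: ElevationMap,
    labels: PatchLabelMap,
    seed: int = 0,
    noise_sd: float = 10.0,
) -> np.ndarray:
    """Emulate an RGB macrophotograph from patch coloration.

    DDP pixels carry an elevated red/green ratio, KDP an elevated green
    channel; additive Gaussian noise; deterministic per seed.  Returns a
    uint8 (ny, nx, 3) image.
    """
    rng = np.random.default_rng(seed)
    ny, nx = labels.shape
    img = np.empty((ny, nx, 3), dtype=float)
    img[:] = _PATCH_COLORS[CDB]
    for code, color in _PATCH_COLORS.items():
        img[labels.labels == code] = color
    img += rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def gen_inlet_profile(
    u_bulk: float,
    n_points: int = 14,
    seed: int = 0,
    noise_rms: float = 0.0,
    height_m: float = 0.005,
) -> np.ndarray:
    """Emulate laser-Doppler velocimetry points across the domain height.

    Samples a quadratic profile vanishing at z = 0 with apex velocity
    u_bulk at the domain top, plus Gaussian noise of SD noise_rms.
    Returns an (n_points, 3) array of (z_m, u_ms, u_rms_ms).
    """
    if n_points < 3:
        raise ValueError("need at least 3 velocimetry points")
    rng = np.random.default_rng(seed)
    z = np.linspace(0.0, height_m, n_points)
    zeta = z / height_m
    u = u_bulk * (2.0 * zeta - zeta**2)
    u = u + rng.normal(0.0, noise_rms, size=n_points)
    u_rms = np.full(n_points, noise_rms)
    return np.column_stack([z, u, u_rms])


def gen_o2_transect(
    domain,
    true_params: ModelParams,
    noise: SensorNoiseSpec,
    light: bool,
    inlet_profile=None,
    inlet_conc: float = 0.3,
    n_profiles: int = 5,
    z_max_mm: float = 2.0,
    flow_label: str = "slow",
    advection: bool = False,
    n_correct: int = 1,
) -> MicroprofileTransect:
    """Forward-model an O2 microsensor transect over a model domain.

    Solves flow and transport at true_params, samples the concentration
    field at n_profiles x-positions in vertical steps of
    noise.vertical_step_mm, and adds Gaussian sensor noise.  The true
    parameters and generation settings are recorded in the transect
    metadata for recovery experiments.  Solver failures propagate.
    """
    from .hydro import solve_flow, solve_transport

    rng = np.random.default_rng(noise.seed)
    flow = solve_flow(domain, true_params, inlet_profile, advection=advection)
    conc = solve_transport(
        domain,
        flow,
        true_params,
        inlet_conc=inlet_conc,
        light=light,
        n_correct=n_correct,
    )

    width_mm = domain.width_m * 1e3
    x_mm = np.linspace(0.15 * width_mm, 0.85 * width_mm, n_profiles)
    step = noise.vertical_step_mm
    z_mm = np.arange(step, min(z_max_mm, domain.height_m * 1e3) + step / 2, step)

    profiles = []
    for x in x_mm:
        c = conc.interp(np.full(z_mm.size, x * 1e-3), z_mm * 1e-3)
        c = c + rng.normal(0.0, noise.sigma_conc, size=c.shape)
        xi = int(np.clip(np.searchsorted(domain.xf, x * 1e-3) - 1, 0, domain.nx - 1))
        profiles.append(
            Profile(
                x_mm=float(x),
                z_mm=z_mm.copy(),
                conc=c,
                surface_z_mm=float(domain.elevation_m[xi] * 1e3),
            )
        )
    return MicroprofileTransect(
        profiles=profiles,
        light=light,
        flow=flow_label,
        metadata={
            "true_params": true_params,
            "seed": noise.seed,
            "sigma_conc": noise.sigma_conc,
            "inlet_conc": inlet_conc,
            "advection": advection,
        },
    )


def local_mean(green: np.ndarray, radius: int) -> np.ndarray:
    """Box local-mean filter of a channel, shared with the segmenter."""
    return uniform_filter(green.astype(float), size=2 * radius + 1)
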