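"""Surface topology, patch classes, geometry and porosity from imagery.

Turns OCT-like intensity volumes into digital elevation models (DEMs),
stitches tile mosaics, classifies patch types from macrophotograph
coloration, and derives the per-patch geometry statistics and porosity
estimates that drive the landscape upscaling.

Conventions: volumes are (nz, ny, nx) with voxel 0 at the substrate
plane; rasters are (ny, nx), row-major, origin upstream-left; heights
in mm; porosity is the void fraction (void voxels / total voxels) of
the sub-surface layer, the reading under which the loose filamentous
patches get the higher value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from skimage.filters import threshold_otsu
from skimage.morphology import dilation, disk, remove_small_holes, remove_small_objects

from .synth import local_mean
from .types import BACKGROUND, CDB, DDP, KDP, PATCH_NAMES, ElevationMap, PatchLabelMap

logger = logging.getLogger(__name__)


def find_substrate_plane(volume: np.ndarray) -> int:
    """Index of the substrate plane: the brightest z-slice (mean
    intensity) within the lowest quartile of the volume — the highly
    reflective flume bottom."""
    nzv = volume.shape[0]
    quart = max(1, nzv // 4)
    means = volume[:quart].reshape(quart, -1).mean(axis=1)
    return int(np.argmax(means))


def extract_dem(
    volume: np.ndarray,
    pixel_mm: float,
    axial_step_mm: float,
    intensity_threshold: int = 130,
    substrate_plane: int | None = None,
    median_size: int = 4,
) -> ElevationMap:
    """Digital elevation model from an OCT intensity volume.

    Per column, the surface is the highest voxel above the intensity
    threshold; height = (surface - substrate) x axial step, clipped at
    zero; a 2D median filter of the given size denoises the raster.
    Columns with no voxel above the threshold get height 0 (count
    logged).
    """
    if volume.ndim != 3:
        raise ValueError("volume must be 3D (nz, ny, nx)")
    ks = find_substrate_plane(volume) if substrate_plane is None else substrate_plane

    above = volume[ks + 1 :] > intensity_threshold
    nz_rem = above.shape[0]
    # highest voxel above threshold per column
    rev_idx = np.argmax(above[::-1], axis=0)
    any_above = above.any(axis=0)
    top = np.where(any_above, nz_rem - 1 - rev_idx, -1)
    n_empty = int((~any_above).sum())
    if n_empty:
        logger.info("extract_dem: %d columns without signal above threshold", n_empty)
    heights = np.where(any_above, (top + 1) * axial_step_mm, 0.0)
    if median_size > 1:
        heights = median_filter(heights, size=median_size, mode="nearest")
    return ElevationMap(heights=heights, pixel_mm=pixel_mm)


def stitch_tiles(
    tiles: list[ElevationMap],
    grid_layout: tuple[int, int],
    overlap_fraction: float = 0.30,
) -> ElevationMap:
    """Translation-based mosaic of DEM tiles (row-major order).

    Overlapping pixels are averaged; the output extent follows from the
    layout arithmetic with the given fractional overlap.
    """
    rows, cols = grid_layout
    if len(tiles) != rows * cols:
        raise ValueError("tile count does not match the grid layout")
    shape0 = tiles[0].shape
    pixel = tiles[0].pixel_mm
    for t in tiles:
        if t.shape != shape0:
            raise ValueError("tiles must share a shape")
        if t.pixel_mm != pixel:
            raise ValueError("tiles must share a resolution")
    ty, tx = shape0
    step_y = int(round(ty * (1.0 - overlap_fraction)))
    step_x = int(round(tx * (1.0 - overlap_fraction)))
    out_y = step_y * (rows - 1) + ty
    out_x = step_x * (cols - 1) + tx
    acc = np.zeros((out_y, out_x))
    cnt = np.zeros((out_y, out_x))
    for r in range(rows):
        for c in range(cols):
            t = tiles[r * cols + c]
            y0, x0 = r * step_y, c * step_x
            acc[y0 : y0 + ty, x0 : x0 + tx] += t.heights
            cnt[y0 : y0 + ty, x0 : x0 + tx] += 1.0
    return ElevationMap(heights=acc / cnt, pixel_mm=pixel)


def thickness_stats(dem: ElevationMap, mask: np.ndarray) -> tuple[float, float]:
    """Median thickness and 0.2-0.8 inter-quantile range (mm) over a mask."""
    h = dem.heights[mask]
    if h.size == 0:
        raise ValueError("empty mask")
    q2, med, q8 = np.quantile(h, [0.2, 0.5, 0.8])
    return float(med), float(q8 - q2)


def biovolume(dem: ElevationMap, mask: np.ndarray | None = None) -> float:
    """Volume beneath the biofilm surface (mm^3): sum of DEM heights
    times the pixel area, over the mask (all pixels if None)."""
    h = dem.heights if mask is None else dem.heights[mask]
    return float(h.sum() * dem.pixel_area_mm2)


@dataclass
class SegmentationConfig:
    """Colour-segmentation thresholds; None means Otsu's criterion."""

    ddp_rg_threshold: float | None = None
    kdp_green_threshold: float | None = None
    local_mean_radius: int = 10
    min_object_px: int = 25
    dilation_px: int = 5


def segment_patches(
    rgb: np.ndarray,
    config: SegmentationConfig | None = None,
    pixel_mm: float = 1.0,
) -> PatchLabelMap:
    """Classify patch types from an RGB macrophotograph.

    DDP from a threshold on the red/green ratio; KDP from a threshold on
    the mean of the green channel and its local-mean filter; small
    objects and holes removed; the KDP mask dilated; KDP takes
    precedence over DDP; the remainder is CDB.
    """
    cfg = config or SegmentationConfig()
    img = rgb.astype(float)
    red, green = img[..., 0], img[..., 1]
    ratio = red / np.maximum(green, 1.0)
    combo = 0.5 * (green + local_mean(green, cfg.local_mean_radius))

    def _threshold(values: np.ndarray, given: float | None) -> float | None:
        if given is not None:
            return given
        if values.max() == values.min():  # no structure to threshold
            return None
        return float(threshold_otsu(values))

    thr_d = _threshold(ratio, cfg.ddp_rg_threshold)
    thr_k = _threshold(combo, cfg.kdp_green_threshold)
    if thr_d is None and thr_k is None:
        warnings.warn("uniform image: no patch structure found, all CDB", stacklevel=2)
        return PatchLabelMap(labels=np.full(rgb.shape[:2], CDB), pixel_mm=pixel_mm)

    def _clean(mask: np.ndarray) -> np.ndarray:
        if cfg.min_object_px > 0:
            mask = remove_small_objects(mask, max_size=cfg.min_object_px - 1)
            mask = remove_small_holes(mask, max_size=cfg.min_object_px - 1)
        return mask

    ddp = _clean(ratio > thr_d) if thr_d is not None else np.zeros_like(ratio, bool)
    kdp = _clean(combo > thr_k) if thr_k is not None else np.zeros_like(ratio, bool)
    if cfg.dilation_px > 0 and kdp.any():
        kdp = dilation(kdp, disk(cfg.dilation_px))

    labels = np.full(rgb.shape[:2], CDB, dtype=np.int8)
    labels[ddp] = DDP
    labels[kdp] = KDP  # precedence over DDP
    return PatchLabelMap(labels=labels, pixel_mm=pixel_mm)


def patch_geometry(dem: ElevationMap, labels: PatchLabelMap) -> pd.DataFrame:
    """Per-patch-type geometry statistics mirroring the survey table.

    Columns: area (mm^2), coverage (% of labelled biofilm area), volume
    (mm^3), volume share (%), height mean and SD (mm); plus a landscape
    totals row.  Missing classes get zeros.
    """
    if dem.shape != labels.shape:
        raise ValueError("DEM and label rasters must share a shape")
    px_area = dem.pixel_area_mm2
    biofilm = labels.labels != BACKGROUND
    total_area = float(biofilm.sum() * px_area)
    total_vol = biovolume(dem, biofilm)

    rows = []
    for code in (CDB, DDP, KDP):
        mask = labels.mask(code)
        area = float(mask.sum() * px_area)
        vol = biovolume(dem, mask)
        h = dem.heights[mask]
        rows.append(
            {
                "patch_type": PATCH_NAMES[code],
                "height_mean_mm": float(h.mean()) if h.size else 0.0,
                "height_sd_mm": float(h.std()) if h.size else 0.0,
                "area_mm2": area,
                "coverage_pct": 100.0 * area / total_area if total_area else 0.0,
                "volume_mm3": vol,
                "volume_pct": 100.0 * vol / total_vol if total_vol else 0.0,
            }
        )
    rows.append(
        {
            "patch_type": "landscape",
            "height_mean_mm": float(dem.heights[biofilm].mean())
            if biofilm.any()
            else 0.0,
            "height_sd_mm": float(dem.heights[biofilm].std()) if biofilm.any() else 0.0,
            "area_mm2": total_area,
            "coverage_pct": 100.0,
            "volume_mm3": total_vol,
            "volume_pct": 100.0,
        }
    )
    return pd.DataFrame(rows)


@dataclass
class PorosityEstimate:
    """Per-patch-type porosity with the two-threshold/two-layer band."""

    by_setting: dict = dc_field(default_factory=dict)  # (threshold, layer_mm) -> median
    low: float = 0.0
    high: float = 0.0
    mid: float = 0.0
    n_columns: int = 0


def porosity(
    volume: np.ndarray,
    dem: ElevationMap,
    labels: PatchLabelMap,
    axial_step_mm: float,
    gray_thresholds: tuple[int, int] = (120, 130),
    layer_depths_mm: tuple[float, float] = (0.1, 0.2),
    max_height_mm: float = 1.2,
    substrate_plane: int | None = None,
) -> dict[str, PorosityEstimate]:
    """Void fraction of the top biofilm layer per patch type.

    For each gray threshold x layer thickness, the column porosity is
    the fraction of sub-surface voxels (in the top layer, below the
    one-voxel surface skin) with gray value below the threshold; the
    per-type value is the median across columns, and the reported band
    is the min-max over the four settings.  Columns protruding beyond
    max_height_mm (the OCT imaging depth) are excluded.  A type with no
    eligible columns raises.
    """
    ks = find_substrate_plane(volume) if substrate_plane is None else substrate_plane
    sub = volume[ks + 1 :]
    nz_rem = sub.shape[0]
    dz = axial_step_mm
    kz = np.arange(nz_rem)[:, None, None]
    h = dem.heights
    # indices below are within `sub`, whose voxel j is volume voxel ks+1+j;
    # the one-voxel surface skin is excluded from the count
    j_surf = np.floor(h / dz) - 1

    present = [c for c in (CDB, DDP, KDP) if labels.mask(c).any()]
    out: dict[str, PorosityEstimate] = {}
    for code in present:
        mask = labels.mask(code) & (h > 0) & (h <= max_height_mm)
        name = PATCH_NAMES[code]
        if not mask.any():
            raise ValueError(f"no eligible columns for patch type {name}")
        est = PorosityEstimate()
        for layer in layer_depths_mm:
            j_lo = np.maximum(np.ceil((h - layer) / dz) - 1, 0)
            in_layer = (kz >= j_lo[None]) & (kz < j_surf[None])
            n_tot = in_layer.sum(axis=0).astype(float)
            eligible = mask & (n_tot > 0)
            if not eligible.any():
                raise ValueError(
                    f"no columns of {name} deep enough for a {layer} mm layer"
                )
            for thr in gray_thresholds:
                void = in_layer & (sub < thr)
                n_void = void.sum(axis=0)
                with np.errstate(invalid="ignore"):
                    frac = np.where(n_tot > 0, n_void / np.maximum(n_tot, 1), np.nan)
                est.by_setting[(thr, layer)] = float(np.median(frac[eligible]))
        vals = list(est.by_setting.values())
        est.low, est.high = float(min(vals)), float(max(vals))
        est.mid = float(np.mean(vals))
        est.n_columns = int(mask.sum())
        out[name] = est
    return out
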