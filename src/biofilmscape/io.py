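"""Readers and writers for the pipeline's on-disk formats.

OCT volumes as multi-page TIFF, DEMs and label maps as single-page TIFF
with a CSV sidecar of raster metadata, microprofile transects as tidy
CSV (transect_id, x_mm, z_mm, conc_mol_m3, light, flow), landscape
specs and run configs as YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import (
    CDB,
    DDP,
    KDP,
    ElevationMap,
    LandscapeSpec,
    MicroprofileTransect,
    PatchLabelMap,
    PatchParams,
    Profile,
)


def write_volume(path: str | Path, volume: np.ndarray) -> None:
    """Multi-page TIFF, one page per z-slice."""
    tifffile.imwrite(path, volume)


def read_volume(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def _write_raster(path: Path, data: np.ndarray, pixel_mm: float) -> None:
    tifffile.imwrite(path, data)
    meta = pd.DataFrame({"key": ["pixel_mm"], "value": [pixel_mm]})
    meta.to_csv(path.with_suffix(".csv"), index=False)


def _read_pixel_mm(path: Path) -> float:
    meta = pd.read_csv(path.with_suffix(".csv"))
    return float(meta.loc[meta["key"] == "pixel_mm", "value"].iloc[0])


def write_dem(path: str | Path, dem: ElevationMap) -> None:
    _write_raster(Path(path), dem.heights.astype(np.float32), dem.pixel_mm)


def read_dem(path: str | Path) -> ElevationMap:
    path = Path(path)
    return ElevationMap(
        heights=tifffile.imread(path).astype(float), pixel_mm=_read_pixel_mm(path)
    )


def write_labels(path: str | Path, labels: PatchLabelMap) -> None:
    _write_raster(Path(path), labels.labels.astype(np.uint8), labels.pixel_mm)


def read_labels(path: str | Path) -> PatchLabelMap:
    path = Path(path)
    return PatchLabelMap(
        labels=tifffile.imread(path).astype(np.int8), pixel_mm=_read_pixel_mm(path)
    )


def write_image(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(path, image)


def read_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def write_transect(path: str | Path, transect: MicroprofileTransect, transect_id=0):
    frames = []
    for p in transect.profiles:
        frames.append(
            pd.DataFrame(
                {
                    "transect_id": transect_id,
                    "x_mm": p.x_mm,
                    "z_mm": p.z_mm,
                    "conc_mol_m3": p.conc,
                    "light": transect.light,
                    "flow": transect.flow,
                    "surface_z_mm": (
                        np.nan if p.surface_z_mm is None else p.surface_z_mm
                    ),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_transect(path: str | Path) -> MicroprofileTransect:
    df = pd.read_csv(path)
    profiles = []
    for x, grp in df.groupby("x_mm"):
        grp = grp.sort_values("z_mm")
        surf = grp["surface_z_mm"].iloc[0] if "surface_z_mm" in grp else np.nan
        profiles.append(
            Profile(
                x_mm=float(x),
                z_mm=grp["z_mm"].to_numpy(),
                conc=grp["conc_mol_m3"].to_numpy(),
                surface_z_mm=None if pd.isna(surf) else float(surf),
            )
        )
    return MicroprofileTransect(
        profiles=profiles,
        light=bool(df["light"].iloc[0]),
        flow=str(df["flow"].iloc[0]),
    )


def write_inlet_points(path: str | Path, points: np.ndarray) -> None:
    pd.DataFrame(points, columns=["z_m", "u_ms", "u_rms_ms"]).to_csv(path, index=False)


def read_inlet_points(path: str | Path) -> np.ndarray:
    return pd.read_csv(path)[["z_m", "u_ms", "u_rms_ms"]].to_numpy()


_PATCH_KEYS = {"CDB": CDB, "DDP": DDP, "KDP": KDP}


def write_landscape_spec(path: str | Path, spec: LandscapeSpec) -> None:
    doc = {
        "domain_size_mm": list(spec.domain_size_mm),
        "pixel_mm": spec.pixel_mm,
        "seed": spec.seed,
        "blob_smooth_mm": spec.blob_smooth_mm,
        "patch_params": {
            name: {
                "mean_height_mm": pp.mean_height_mm,
                "sd_height_mm": pp.sd_height_mm,
                "target_coverage_fraction": pp.target_coverage_fraction,
                "target_porosity": pp.target_porosity,
            }
            for name, code in _PATCH_KEYS.items()
            if (pp := spec.patch_params.get(code)) is not None
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_landscape_spec(path: str | Path) -> LandscapeSpec:
    doc = yaml.safe_load(Path(path).read_text())
    return LandscapeSpec(
        domain_size_mm=tuple(doc["domain_size_mm"]),
        pixel_mm=float(doc["pixel_mm"]),
        seed=int(doc.get("seed", 0)),
        blob_smooth_mm=float(doc.get("blob_smooth_mm", 1.0)),
        patch_params={
            _PATCH_KEYS[name]: PatchParams(**vals)
            for name, vals in doc["patch_params"].items()
        },
    )
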