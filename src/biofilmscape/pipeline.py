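"""End-to-end pipeline orchestration with config, seeds and provenance.

Runs any contiguous subset of the stages
synth -> imaging -> profiles -> hydro -> fit -> upscale
from a YAML run configuration, writing all artifacts plus a provenance
manifest (package/library versions, seeds, config hash, per-stage
artifact checksums) into a run directory.  Deterministic stages are
idempotent under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, datasets, imaging, io, synth, upscale
from .fit import fit_parameters
from .hydro import (
    GridConfig,
    build_domain,
    fit_inlet_profile,
    flux_decomposition,
    internal_velocity_stats,
    mass_conservation_residual,
    solve_flow,
    solve_transport,
    wall_shear_dbl,
)
from .profiles import pool_distributions
from .types import (
    CDB,
    DDP,
    KDP,
    FitSpec,
    LandscapeSpec,
    ModelParams,
    PatchBudget,
    PatchParams,
    SensorNoiseSpec,
)

logger = logging.getLogger(__name__)

STAGES = ["synth", "imaging", "profiles", "hydro", "fit", "upscale"]
_ALLOWED_KEYS = {
    "seed",
    "stages",
    "flow",
    "landscape",
    "oct",
    "segmentation",
    "hydro",
    "transect",
    "fit",
    "upscale",
    "inputs",
}
_PATCH_KEYS = {"CDB": CDB, "DDP": DDP, "KDP": KDP}


class PipelineError(RuntimeError):
    pass


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    unknown = set(cfg) - _ALLOWED_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    stages = cfg.get("stages", STAGES)
    idx = [STAGES.index(s) for s in stages]
    if sorted(idx) != idx or idx != list(range(idx[0], idx[-1] + 1)):
        raise ValueError("stages must be a contiguous, ordered subset")
    for key, path in (cfg.get("inputs") or {}).items():
        if not Path(path).exists():
            raise FileNotFoundError(f"configured input '{key}' missing: {path}")


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _landscape_spec(cfg: dict, seed: int) -> LandscapeSpec:
    lc = cfg.get("landscape") or {}
    geometry = datasets.patch_geometry_table()
    flow = cfg.get("flow", "slow")
    rows = geometry[geometry["flow"] == flow].set_index("patch_type")
    default_params = {}
    total = rows["area_mm2"].sum()
    for name, code in _PATCH_KEYS.items():
        r = rows.loc[name]
        default_params[code] = PatchParams(
            mean_height_mm=float(r["height_mean_mm"]),
            sd_height_mm=float(r["height_sd_mm"]),
            target_coverage_fraction=float(r["area_mm2"] / total),
            target_porosity=0.5,
        )
    patch_params = default_params
    if "patch_params" in lc:
        patch_params = {
            _PATCH_KEYS[name]: PatchParams(**vals)
            for name, vals in lc["patch_params"].items()
        }
    return LandscapeSpec(
        domain_size_mm=tuple(lc.get("domain_size_mm", [8.0, 8.0])),
        pixel_mm=float(lc.get("pixel_mm", 0.05)),
        patch_params=patch_params,
        seed=seed,
        blob_smooth_mm=float(lc.get("blob_smooth_mm", 1.0)),
    )


def _transport_params(cfg: dict, patch: str) -> ModelParams:
    flow = cfg.get("flow", "slow")
    tab = datasets.transport_parameters_table()
    row = tab[(tab["flow"] == flow) & (tab["patch_type"] == patch)].iloc[0]
    prt = float(row["prandtl_t"])
    return ModelParams(
        porosity=float(row["porosity"]),
        permeability_m2=float(row["permeability_m2"]),
        c_eff_diff=float(row["c_eff_diff"]),
        prandtl_t=prt,
        eddy_visc_m2s=float(row["eddy_diff_m2s"]) * prt,
    )


def _reference_rate(cfg: dict, patch: str, light: bool) -> float:
    flow = cfg.get("flow", "slow")
    tab = datasets.metabolic_rates_table()
    row = tab[(tab["flow"] == flow) & (tab["patch_type"] == patch)].iloc[0]
    # table units are mmol m^-3 s^-1; the solver works in mol m^-3 s^-1
    return float(row["np_vol" if light else "r_vol"]) * 1e-3


def cross_section(dem, labels, code: int, width_mm: float) -> np.ndarray:
    """Elevation profile (mm) along the row richest in the given patch
    type, windowed to width_mm around the patch centroid."""
    mask = labels.labels == code
    if not mask.any():
        raise ValueError(f"no pixels of patch type {code} in the label map")
    row = int(np.argmax(mask.sum(axis=1)))
    cols = np.flatnonzero(mask[row])
    centre = int(cols.mean())
    half = int(round(width_mm / dem.pixel_mm / 2))
    lo = max(0, centre - half)
    hi = min(dem.shape[1], centre + half)
    return dem.heights[row, lo:hi]


def run_pipeline(config: dict | str | Path, outdir: str | Path, seed: int | None = None):
    """Execute the configured stages, returning the manifest dict.

    Artifacts are written into outdir; a failure in any stage aborts the
    run but preserves partial artifacts and records the failure in the
    manifest.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0)) if seed is None else int(seed)
    stages = config.get("stages", STAGES)

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "seed": seed,
        "config_hash": _config_hash(config),
        "stages": {},
    }

    def artifact(name: str) -> Path:
        return outdir / name

    def record(stage: str, paths: list[Path]) -> None:
        manifest["stages"][stage] = {
            "status": "ok",
            "artifacts": {p.name: _sha256(p) for p in paths},
        }

    def require(name: str, key: str) -> Path:
        override = (config.get("inputs") or {}).get(key)
        p = Path(override) if override else artifact(name)
        if not p.exists():
            raise FileNotFoundError(f"required input for this stage missing: {p}")
        return p

    try:
        if "synth" in stages:
            spec = _landscape_spec(config, seed)
            dem_true, labels_true = synth.gen_landscape(spec)
            oct_cfg = config.get("oct") or {}
            axial = float(oct_cfg.get("axial_step_mm", 0.01))
            vol = synth.gen_oct_volume(dem_true, labels_true, spec, axial_step_mm=axial)
            photo = synth.gen_macrophoto(dem_true, labels_true, seed=seed)
            u_bulk = datasets.FLOW_VELOCITY_MS[config.get("flow", "slow")]
            inlet = synth.gen_inlet_profile(u_bulk, seed=seed)
            io.write_dem(artifact("dem_true.tif"), dem_true)
            io.write_labels(artifact("labels_true.tif"), labels_true)
            io.write_volume(artifact("oct.tif"), vol)
            io.write_image(artifact("photo.tif"), photo)
            io.write_inlet_points(artifact("inlet.csv"), inlet)
            io.write_landscape_spec(artifact("landscape.yaml"), spec)
            (outdir / "oct_meta.yaml").write_text(
                yaml.safe_dump({"axial_step_mm": axial, "pixel_mm": spec.pixel_mm})
            )
            record(
                "synth",
                [
                    artifact(n)
                    for n in (
                        "dem_true.tif",
                        "labels_true.tif",
                        "oct.tif",
                        "photo.tif",
                        "inlet.csv",
                        "landscape.yaml",
                        "oct_meta.yaml",
                    )
                ],
            )

        if "imaging" in stages:
            meta = yaml.safe_load(require("oct_meta.yaml", "oct_meta").read_text())
            vol = io.read_volume(require("oct.tif", "oct"))
            photo = io.read_image(require("photo.tif", "photo"))
            dem = imaging.extract_dem(
                vol, meta["pixel_mm"], meta["axial_step_mm"]
            )
            seg_cfg = imaging.SegmentationConfig(**(config.get("segmentation") or {}))
            labels = imaging.segment_patches(photo, seg_cfg, pixel_mm=meta["pixel_mm"])
            geometry = imaging.patch_geometry(dem, labels)
            poro = imaging.porosity(vol, dem, labels, meta["axial_step_mm"])
            io.write_dem(artifact("dem.tif"), dem)
            io.write_labels(artifact("labels.tif"), labels)
            geometry.to_csv(artifact("geometry.csv"), index=False)
            pd.DataFrame(
                [
                    {"patch_type": name, "low": e.low, "mid": e.mid, "high": e.high}
                    for name, e in poro.items()
                ]
            ).to_csv(artifact("porosity.csv"), index=False)
            record(
                "imaging",
                [artifact(n) for n in ("dem.tif", "labels.tif", "geometry.csv", "porosity.csv")],
            )

        hydro_cfg = config.get("hydro") or {}
        grid = GridConfig(
            nx=int(hydro_cfg.get("nx", 40)),
            dz_fine_m=float(hydro_cfg.get("dz_fine_m", 5e-5)),
            smooth_sigma_mm=float(hydro_cfg.get("smooth_sigma_mm", 0.2)),
        )
        width_mm = float(hydro_cfg.get("width_mm", 4.0))
        tr_cfg = config.get("transect") or {}
        inlet_conc = float(tr_cfg.get("inlet_conc", 0.3))

        if set(stages) & {"profiles", "hydro", "fit"}:
            dem = io.read_dem(require("dem.tif", "dem"))
            labels = io.read_labels(require("labels.tif", "labels"))
            inlet_pts = io.read_inlet_points(require("inlet.csv", "inlet"))
            inlet_fn = fit_inlet_profile(inlet_pts)
            domains = {}
            for name, code in _PATCH_KEYS.items():
                try:
                    section = cross_section(dem, labels, code, width_mm)
                except ValueError:
                    continue
                domains[name] = build_domain(section, width_mm, grid)

        if "profiles" in stages:
            transects = []
            paths = []
            for j, (name, dom) in enumerate(domains.items()):
                params = _transport_params(config, name)
                for light in (False, True):
                    noise = SensorNoiseSpec(
                        sigma_conc=float(tr_cfg.get("sigma_conc", 2e-3)),
                        seed=seed + 13 * j + int(light),
                    )
                    params_l = params.replace(
                        rate_mol_m3s=_reference_rate(config, name, light)
                    )
                    t = synth.gen_o2_transect(
                        dom,
                        params_l,
                        noise,
                        light,
                        inlet_profile=inlet_fn,
                        inlet_conc=inlet_conc,
                        flow_label=config.get("flow", "slow"),
                    )
                    t.patch_type = _PATCH_KEYS[name]
                    transects.append(t)
                    p = artifact(f"transect_{name}_{'light' if light else 'dark'}.csv")
                    io.write_transect(p, t, transect_id=f"{name}_{light}")
                    paths.append(p)
            pooled, summary = pool_distributions(transects)
            pooled.to_csv(artifact("pooled_samples.csv"), index=False)
            summary.to_csv(artifact("pooled_summary.csv"), index=False)
            record("profiles", paths + [artifact("pooled_samples.csv"), artifact("pooled_summary.csv")])

        if "hydro" in stages:
            rows = []
            for name, dom in domains.items():
                params = _transport_params(config, name).replace(
                    rate_mol_m3s=_reference_rate(config, name, light=False)
                )
                flow = solve_flow(dom, params, inlet_fn, advection=True)
                conc = solve_transport(dom, flow, params, inlet_conc=inlet_conc)
                fd = flux_decomposition(dom, flow, conc, params)
                ws = wall_shear_dbl(dom, flow, params)
                ivs = internal_velocity_stats(dom, flow, params)
                rows.append(
                    {
                        "patch_type": name,
                        "cells": dom.cell_count,
                        "mass_residual": mass_conservation_residual(dom, flow),
                        "jc_jd_mean": fd.biofilm_mean,
                        "jc_jd_median": fd.biofilm_median,
                        "surface_advective_fraction": fd.surface_advective_fraction,
                        "tau_pa": ws["tau_pa"],
                        "u_star_ms": ws["u_star_ms"],
                        "dbl_scale_m": ws["dbl_scale_m"],
                        "internal_speed_ms": ivs["mean_speed_ms"],
                    }
                )
                np.savez_compressed(
                    artifact(f"fields_{name}.npz"),
                    u=flow.u, v=flow.v, p=flow.p, c=conc.c,
                    xf=dom.xf, zf=dom.zf, bio=dom.bio,
                )
            pd.DataFrame(rows).to_csv(artifact("hydro_summary.csv"), index=False)
            record("hydro", [artifact("hydro_summary.csv")])

        if "fit" in stages:
            fit_cfg = config.get("fit") or {}
            rows = []
            for name, dom in domains.items():
                params = _transport_params(config, name)
                fitted = {}
                for light in (False, True):
                    t = io.read_transect(
                        require(
                            f"transect_{name}_{'light' if light else 'dark'}.csv",
                            f"transect_{name}_{light}",
                        )
                    )
                    t.light = light
                    bounds = (-6e-3, -1e-5) if not light else (1e-5, 1e-2)
                    spec = FitSpec(
                        free=["rate_mol_m3s"],
                        bounds={"rate_mol_m3s": bounds},
                        init={"rate_mol_m3s": sum(bounds) / 2},
                        max_iter=int(fit_cfg.get("max_iter", 60)),
                        restarts=int(fit_cfg.get("restarts", 1)),
                    )
                    res = fit_parameters(
                        dom, t, spec, base_params=params,
                        inlet_profile=inlet_fn, inlet_conc=inlet_conc, seed=seed,
                    )
                    fitted["np_vol" if light else "r_vol"] = (
                        res.params.rate_mol_m3s * 1e3
                    )
                    fitted[
                        "pearson_light" if light else "pearson_dark"
                    ] = float(np.nanmean(res.correlations))
                rows.append({"patch_type": name, **fitted})
            pd.DataFrame(rows).to_csv(artifact("fitted_rates.csv"), index=False)
            record("fit", [artifact("fitted_rates.csv")])

        if "upscale" in stages:
            geometry = pd.read_csv(require("geometry.csv", "geometry"))
            rates = pd.read_csv(require("fitted_rates.csv", "fitted_rates"))
            budgets = []
            for _, r in rates.iterrows():
                g = geometry[geometry["patch_type"] == r["patch_type"]].iloc[0]
                budgets.append(
                    PatchBudget(
                        patch_type=r["patch_type"],
                        r_vol=float(r["r_vol"]),
                        np_vol=float(r["np_vol"]),
                        area_mm2=float(g["area_mm2"]),
                        volume_mm3=float(g["volume_mm3"]),
                    )
                )
            table = upscale.budget_table(budgets)
            table.to_csv(artifact("budget.csv"), index=False)
            record("upscale", [artifact("budget.csv")])
    except Exception as exc:
        manifest["stages"]["failed"] = {"status": "error", "message": str(exc)}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise PipelineError(f"pipeline stage failed: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
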