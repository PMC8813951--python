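"""Shared fixtures: reference landscape specs and small solver domains."""

from __future__ import annotations

import numpy as np
import pytest

from biofilmscape.hydro import GridConfig, build_domain
from biofilmscape.types import CDB, DDP, KDP, LandscapeSpec, ModelParams, PatchParams


@pytest.fixture(scope="session")
def survey_patch_params() -> dict[int, PatchParams]:
    """Slow-flow survey targets: heights (mm), coverages, porosities."""
    return {
        CDB: PatchParams(0.39, 0.15, 0.700, 0.40),
        DDP: PatchParams(0.58, 0.15, 0.202, 0.47),
        KDP: PatchParams(1.09, 0.24, 0.098, 0.58),
    }


@pytest.fixture(scope="session")
def survey_spec(survey_patch_params) -> LandscapeSpec:
    return LandscapeSpec(
        domain_size_mm=(10.0, 10.0),
        pixel_mm=0.05,
        patch_params=survey_patch_params,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_spec(survey_patch_params) -> LandscapeSpec:
    """Small raster for volume-based round trips."""
    return LandscapeSpec(
        domain_size_mm=(3.0, 3.0),
        pixel_mm=0.05,
        patch_params=survey_patch_params,
        seed=7,
    )


@pytest.fixture(scope="session")
def bump_domain():
    """KDP-like protruding patch cross-section on a thin base."""
    x = np.linspace(0, 4, 40)
    elev = 0.3 + 0.5 * np.exp(-(((x - 2) / 0.8) ** 2))
    return build_domain(elev, 4.0, GridConfig(nx=32, dz_fine_m=5e-5, dz_max_m=3e-4))


@pytest.fixture(scope="session")
def column_grid_config():
    """Uniform 64-cell column over the 5 mm domain height (oracle grids)."""
    return GridConfig(nx=8, height_m=0.005, dz_fine_m=0.005 / 64, dz_max_m=0.005 / 64, band_m=0.0)


@pytest.fixture()
def still_water_params() -> ModelParams:
    return ModelParams(eddy_visc_m2s=0.0)
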