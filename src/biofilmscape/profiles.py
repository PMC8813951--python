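"""Microsensor O2 profile processing and spatial gradient analysis.

Linear two-point calibration, drift correction against bulk readings,
surface location from the profile inflection point, Delaunay
triangulation of transects into 2D concentration-gradient fields, and
pooling of below-surface measurements by patch type / light / flow.

Angle convention for gradients: 0 degrees points downstream (+x) and 90
degrees towards the substrate (-z); angles are reported in [0, 360).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError

from .types import MicroprofileTransect, PATCH_NAMES


def calibrate_linear(
    raw_signals: np.ndarray,
    cal_air_signal: float,
    cal_zero_signal: float,
    conc_air_sat: float,
) -> np.ndarray:
    """Two-point linear calibration of raw sensor readings.

    The affine map sends the anoxic (ascorbate) reading to 0 and the
    air-saturated reading to conc_air_sat (mol m^-3).
    """
    if cal_air_signal == cal_zero_signal:
        raise ValueError("calibration signals must differ")
    raw = np.asarray(raw_signals, dtype=float)
    return (raw - cal_zero_signal) / (cal_air_signal - cal_zero_signal) * conc_air_sat


def drift_correct(
    times: np.ndarray,
    values: np.ndarray,
    bulk_times: np.ndarray,
    bulk_values: np.ndarray,
    reference_bulk: float | None = None,
) -> np.ndarray:
    """Compensate sensor drift by linear interpolation of bulk readings.

    Each sample is rescaled so the interpolated bulk concentration at
    its timestamp maps to the reference bulk concentration (the first
    bulk reading unless given).  Bulk readings must bracket the data.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size == 0:
        return values.copy()
    bt = np.asarray(bulk_times, dtype=float)
    bv = np.asarray(bulk_values, dtype=float)
    if bt.size < 2 or bt.min() > times.min() or bt.max() < times.max():
        raise ValueError("bulk readings must bracket the measurement times")
    ref = bv[0] if reference_bulk is None else reference_bulk
    bulk_at = np.interp(times, bt, bv)
    if np.any(bulk_at == 0):
        raise ValueError("interpolated bulk concentration of zero")
    return values * (ref / bulk_at)


def _second_derivative(z: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Centred second derivative after 3-point moving-average smoothing."""
    cs = c.copy()
    cs[1:-1] = (c[:-2] + c[1:-1] + c[2:]) / 3.0
    return np.gradient(np.gradient(cs, z), z)


def locate_surface(
    profile_light,
    profile_dark,
    oct_height_mm: float,
    window_mm: float = 0.3,
) -> float:
    """Refine the biofilm surface position from profile curvature.

    The surface is the z of maximum |d2c/dz2| of the mean of the light
    and dark profiles, within +/- window_mm of the OCT-indicated height.
    Falls back to the OCT height (with a warning) when the window lies
    outside the profiles or the profiles carry no curvature.
    """
    z = profile_light.z_mm
    c_light = profile_light.conc
    c_dark = np.interp(z, profile_dark.z_mm, profile_dark.conc)
    c = 0.5 * (c_light + c_dark)

    sel = (z >= oct_height_mm - window_mm) & (z <= oct_height_mm + window_mm)
    if sel.sum() < 3:
        warnings.warn(
            "surface window outside profile; falling back to OCT height",
            stacklevel=2,
        )
        return float(oct_height_mm)
    d2 = np.abs(_second_derivative(z, c))
    d2 = np.where(sel, d2, -np.inf)
    scale = max(np.abs(c).max(), 1e-30)
    span = max(z[-1] - z[0], 1e-30)
    if d2.max() <= 1e-9 * scale / span**2:  # flat profile: no inflection
        warnings.warn(
            "no curvature in profile; falling back to OCT height", stacklevel=2
        )
        return float(oct_height_mm)
    return float(z[int(np.argmax(d2))])


@dataclass
class GradientField:
    """Triangulated 2D concentration field with nodal gradients.

    points: (n, 2) sensor coordinates (x_mm, z_mm); conc at nodes;
    simplices from the Delaunay triangulation; grad: (n, 2) nodal
    gradient (mol m^-3 mm^-1), area-weighted over incident triangles;
    magnitude and angle_deg per the package convention (0 = downstream,
    90 = towards the substrate).
    """

    points: np.ndarray
    conc: np.ndarray
    simplices: np.ndarray
    grad: np.ndarray
    magnitude: np.ndarray
    angle_deg: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_mm": self.points[:, 0],
                "z_mm": self.points[:, 1],
                "conc_mol_m3": self.conc,
                "grad_mag": self.magnitude,
                "grad_angle_deg": self.angle_deg,
            }
        )


def triangulate_field(transect: MicroprofileTransect) -> GradientField:
    """Triangulate a transect and estimate nodal concentration gradients.

    Per-triangle gradients come from the exact plane fit (linear
    interpolation), so affine concentration fields are recovered to
    machine precision; nodal gradients are area-weighted means of the
    incident triangles.
    """
    x, z, c = transect.points()
    if x.size < 3:
        raise ValueError("need at least 3 sample points")
    pts = np.column_stack([x, z])
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise ValueError("sample points are collinear") from exc

    grad_nodes = np.zeros((x.size, 2))
    weight = np.zeros(x.size)
    for simplex in tri.simplices:
        p = pts[simplex]
        v = c[simplex]
        mat = np.column_stack([p[1] - p[0], p[2] - p[0]]).T  # rows: edge vectors
        rhs = np.array([v[1] - v[0], v[2] - v[0]])
        g = np.linalg.solve(mat, rhs)
        e1, e2 = p[1] - p[0], p[2] - p[0]
        area = 0.5 * abs(e1[0] * e2[1] - e1[1] * e2[0])
        for node in simplex:
            grad_nodes[node] += area * g
            weight[node] += area
    ok = weight > 0
    grad_nodes[ok] /= weight[ok, None]

    magnitude = np.hypot(grad_nodes[:, 0], grad_nodes[:, 1])
    # 0 deg downstream (+x), 90 deg towards the substrate (-z)
    angle = np.degrees(np.arctan2(-grad_nodes[:, 1], grad_nodes[:, 0])) % 360.0
    return GradientField(
        points=pts,
        conc=c,
        simplices=tri.simplices,
        grad=grad_nodes,
        magnitude=magnitude,
        angle_deg=angle,
    )


def pool_distributions(
    transects: list[MicroprofileTransect],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pool below-surface samples by patch type, light and flow.

    Only samples strictly below each profile's aligned surface are
    included (profiles without a surface position are skipped).
    Returns (samples, summary): one row per pooled sample, and per-group
    counts with quartiles.
    """
    rows = []
    for t in transects:
        patch = (
            PATCH_NAMES.get(t.patch_type, str(t.patch_type))
            if t.patch_type is not None
            else "unknown"
        )
        for p in t.profiles:
            if p.surface_z_mm is None:
                continue
            below = p.z_mm < p.surface_z_mm
            for z, c in zip(p.z_mm[below], p.conc[below]):
                rows.append(
                    {
                        "patch_type": patch,
                        "light": bool(t.light),
                        "flow": t.flow,
                        "x_mm": p.x_mm,
                        "z_mm": float(z),
                        "conc_mol_m3": float(c),
                    }
                )
    samples = pd.DataFrame(
        rows,
        columns=["patch_type", "light", "flow", "x_mm", "z_mm", "conc_mol_m3"],
    )
    if samples.empty:
        summary = pd.DataFrame(
            columns=["patch_type", "light", "flow", "n", "q25", "median", "q75"]
        )
        return samples, summary
    grouped = samples.groupby(["patch_type", "light", "flow"])["conc_mol_m3"]
    summary = grouped.agg(
        n="count",
        q25=lambda s: s.quantile(0.25),
        median="median",
        q75=lambda s: s.quantile(0.75),
    ).reset_index()
    return samples, summary
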