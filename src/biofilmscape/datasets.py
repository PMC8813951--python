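"""Reference survey constants of the gradient-flume biofilm experiment.

Printed summary tables of the 30-day flume survey this package is
designed around: per-patch-type geometry from OCT/macro-photography
imaging and the model-fitted volumetric metabolic rates, under a slow
(~0.06 m/s) and a fast (~0.13 m/s) flow condition.  These serve as
worked-example inputs for the upscaling chain and as generator targets
for the synthetic landscapes.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

# geometry per flow condition and patch type: mean/SD surface height (mm),
# projected area (mm^2), coverage (% of the analyzed area), biovolume
# (mm^3), volume share (%)
_GEOMETRY_CSV = """\
flow,patch_type,height_mean_mm,height_sd_mm,area_mm2,coverage_pct,volume_mm3,volume_pct
slow,CDB,0.39,0.15,1411,70.0,591,57
slow,DDP,0.58,0.15,408,20.2,253,25
slow,KDP,1.09,0.24,197,9.8,189,18
fast,CDB,0.38,0.11,1145,71.5,440,57
fast,DDP,0.51,0.13,314,19.6,174,23
fast,KDP,1.27,0.27,142,8.9,152,20
"""

# fitted volumetric rates (mmol O2 m^-3 s^-1): dark respiration R
# (negative) and net photosynthesis NP (positive)
_RATES_CSV = """\
flow,patch_type,r_vol,np_vol
slow,CDB,-0.98,5.1
slow,DDP,-0.55,3.0
slow,KDP,-0.88,2.5
fast,CDB,-1.61,5.38
fast,DDP,-1.11,2.06
fast,KDP,-1.37,1.1
"""

# fitted transport parameters per condition: porosity (-), effective
# diffusivity ratio D_eff/D_aq (-), permeability (m^2), turbulent
# Prandtl number (-), eddy diffusivity (m^2/s)
_TRANSPORT_CSV = """\
flow,patch_type,porosity,c_eff_diff,permeability_m2,prandtl_t,eddy_diff_m2s
slow,CDB,0.36,0.7,1e-10,0.98,1e-5
slow,DDP,0.47,0.7,0.6e-10,0.6,1.2e-5
slow,KDP,0.58,0.8,1e-10,0.95,1.4e-5
fast,CDB,0.62,0.7,1e-10,1.0,1.8e-5
fast,DDP,0.41,0.5,0.5e-10,1.0,1.2e-5
fast,KDP,0.86,0.9,2e-10,0.72,1.2e-5
"""

# bulk flow velocities (m/s) at the two survey sections
FLOW_VELOCITY_MS = {"slow": 0.06, "fast": 0.13}
DISCHARGE_M3S = 2.22e-4
WATER_DEPTH_M = 0.022


def patch_geometry_table() -> pd.DataFrame:
    """Per-patch geometry of the reference survey (both flow conditions)."""
    return pd.read_csv(StringIO(_GEOMETRY_CSV))


def metabolic_rates_table() -> pd.DataFrame:
    """Fitted volumetric respiration/photosynthesis rates of the survey."""
    return pd.read_csv(StringIO(_RATES_CSV))


def transport_parameters_table() -> pd.DataFrame:
    """Fitted porous-transport parameters of the survey."""
    return pd.read_csv(StringIO(_TRANSPORT_CSV))
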