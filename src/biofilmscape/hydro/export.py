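"""Field serialization for visualization tools."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .domain import ModelDomain
from .flow import FlowField
from .transport import ConcField


def export_vtk(
    path: str | Path,
    domain: ModelDomain,
    flow: FlowField | None = None,
    conc: ConcField | None = None,
) -> None:
    """Write cell data on the model grid as a legacy-ASCII VTK
    rectilinear grid (loadable by ParaView/VisIt).

    Cell fields: biofilm indicator, and if given velocity (cell-centred,
    m/s), pressure (Pa) and O2 concentration (mol m^-3).
    """
    nx, nz = domain.nx, domain.nz
    lines = [
        "# vtk DataFile Version 3.0",
        "biofilm model fields",
        "ASCII",
        "DATASET RECTILINEAR_GRID",
        f"DIMENSIONS {nx + 1} {nz + 1} 1",
        f"X_COORDINATES {nx + 1} double",
        " ".join(f"{x:.9e}" for x in domain.xf),
        f"Y_COORDINATES {nz + 1} double",
        " ".join(f"{z:.9e}" for z in domain.zf),
        "Z_COORDINATES 1 double",
        "0.0",
        f"CELL_DATA {nx * nz}",
    ]

    def scalar(name: str, data: np.ndarray) -> None:
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        # VTK cell ordering: x varies fastest
        lines.extend(f"{v:.9e}" for v in data.T.ravel())

    scalar("biofilm", domain.bio.astype(float))
    if flow is not None:
        uc, vc = flow.cell_velocity()
        lines.append("VECTORS velocity double")
        lines.extend(
            f"{uc[i, k]:.9e} {vc[i, k]:.9e} 0.0"
            for k in range(nz)
            for i in range(nx)
        )
        scalar("pressure", flow.p)
    if conc is not None:
        scalar("oxygen", conc.c)
    Path(path).write_text("\n".join(lines) + "\n")
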