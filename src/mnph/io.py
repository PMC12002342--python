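"""Plain-text output helpers: legacy-ASCII VTK export of (r, z) fields.

The axisymmetric temperature and damage fields live on a uniform structured
(r, z) node grid, which maps directly onto the legacy VTK STRUCTURED_POINTS
format (readable by ParaView and VisIt).  The writer emits plain ASCII only.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_vtk_structured", "write_probe_csv"]


def write_vtk_structured(path, r, z, fields: dict, comment="mnph axisymmetric field"):
    """Write one or more (n_r, n_z) nodal scalar fields as legacy ASCII VTK.

    The (r, z) plane is written as the (x, y) plane of a one-slab-thick
    structured-points dataset.
    """
    r = np.asarray(r, dtype=float)
    z = np.asarray(z, dtype=float)
    n_r, n_z = len(r), len(z)
    for name, data in fields.items():
        if np.asarray(data).shape != (n_r, n_z):
            raise ValueError(f"field {name!r} shape differs from grid ({n_r}, {n_z})")
    lines = [
        "# vtk DataFile Version 3.0",
        comment,
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {n_r} {n_z} 1",
        f"ORIGIN {r[0]:.9g} {z[0]:.9g} 0",
        f"SPACING {(r[1] - r[0]):.9g} {(z[1] - z[0]):.9g} 1",
        f"POINT_DATA {n_r * n_z}",
    ]
    for name, data in fields.items():
        data = np.asarray(data, dtype=float)
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        # VTK point order: x (here r) varies fastest
        lines.extend(f"{v:.9g}" for v in data.T.ravel())
    Path(path).write_text("\n".join(lines) + "\n")


def write_probe_csv(path, history, celsius=True):
    """Per-step probe traces of a finished run as CSV (time plus P1..Pn)."""
    import pandas as pd

    vals = history.probe_values - 273.15 if celsius else history.probe_values
    df = pd.DataFrame(vals, columns=list(history.probe_names))
    df.insert(0, "time_s", history.probe_times)
    df.to_csv(path, index=False)
    return df
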