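"""File writers shared by all components: trajectory CSV, legacy-ASCII VTK
structured-points fields, and provenance JSON.

The VTK writer emits the plain-text legacy format (``DATASET
STRUCTURED_POINTS`` with one ``SCALARS`` block per field) readable by any
standard VTK-aware viewer; values are printed with ``repr`` round-trip
precision so a write/read cycle is bit-exact.
"""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from .grids import Grid, TissueState
from .simulate import TRAJECTORY_COLUMNS


def write_trajectory(traj: pd.DataFrame, path) -> None:
    cols = [c for c in TRAJECTORY_COLUMNS if c in traj.columns]
    traj.to_csv(path, index=False, columns=cols,
                float_format=None)  # pandas default keeps full repr precision


def read_trajectory(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_fields(state: TissueState, path, fields: dict | None = None) -> None:
    """Write all state fields (or a named subset) as legacy-ASCII VTK."""
    grid = state.grid
    data = fields or state.field_dict()
    dims = list(grid.shape) + [1] * (3 - grid.dim)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"lymphsim fields t={state.t_day!r} day\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {dims[0]} {dims[1]} {dims[2]}\n")
        fh.write(f"ORIGIN {0.5 * grid.h!r} {0.5 * grid.h!r} "
                 f"{0.5 * grid.h if grid.dim == 3 else 0.0!r}\n")
        fh.write(f"SPACING {grid.h!r} {grid.h!r} {grid.h!r}\n")
        fh.write(f"POINT_DATA {int(np.prod(grid.shape))}\n")
        for name, arr in data.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            flat = np.asarray(arr).reshape(-1, order="F")  # VTK is x-fastest
            fh.write("\n".join(repr(float(v)) for v in flat))
            fh.write("\n")


def read_fields(path):
    """Read a legacy-ASCII VTK file written by :func:`write_fields`.

    Returns ``(fields, meta)`` with fields as arrays in this package's
    index order and meta holding dimensions/origin/spacing/time.
    """
    fields = {}
    meta = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    shape3 = None
    while i < len(lines):
        tok = lines[i].split()
        if not tok:
            i += 1
            continue
        key = tok[0].upper()
        if key == "DIMENSIONS":
            shape3 = tuple(int(v) for v in tok[1:4])
            meta["dimensions"] = shape3
        elif key in ("ORIGIN", "SPACING"):
            meta[key.lower()] = tuple(float(v) for v in tok[1:4])
        elif lines[i].startswith("lymphsim fields t="):
            meta["t_day"] = float(lines[i].split("=")[1].split()[0])
        elif key == "SCALARS":
            name = tok[1]
            npts = int(np.prod(shape3))
            vals = []
            j = i + 2   # skip LOOKUP_TABLE line
            while len(vals) < npts:
                vals.extend(float(v) for v in lines[j].split())
                j += 1
            shape = tuple(d for d in shape3 if d > 1) or (1,)
            fields[name] = np.asarray(vals).reshape(shape, order="F")
            i = j
            continue
        i += 1
    return fields, meta


def write_provenance(path, params, seed, extra: dict | None = None) -> None:
    """Provenance JSON sufficient to reproduce a run exactly."""
    info = {
        "package": "lymphsim",
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": seed,
        "parameters": json.loads(params.to_json()),
    }
    if extra:
        info.update(extra)
    with open(path, "w") as fh:
        json.dump(info, fh, indent=2, sort_keys=True)
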