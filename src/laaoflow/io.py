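"""File interfaces: STL surfaces, legacy-VTK field dumps, HDF5 checkpoints,
YAML configurations."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .anatomy import DomainGrid
from .hemo import FlowState


def write_stl(mesh, path):
    """Export a trimesh surface as STL."""
    mesh.export(str(path))


def write_vtk_cells(grid: DomainGrid, fields: dict, path):
    """Minimal legacy-VTK STRUCTURED_POINTS ASCII writer for per-cell fields.

    Readable by standard visualization tools; values are written in x-fastest
    order as VTK expects.
    """
    nx, ny, nz = grid.shape
    lines = [
        "# vtk DataFile Version 3.0",
        "laaoflow cell fields",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}",
        f"ORIGIN {grid.origin[0]} {grid.origin[1]} {grid.origin[2]}",
        f"SPACING {grid.spacing} {grid.spacing} {grid.spacing}",
        f"CELL_DATA {nx * ny * nz}",
    ]
    for name, arr in fields.items():
        arr = np.asarray(arr)
        flat = arr.transpose(2, 1, 0).reshape(-1)
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(" ".join(f"{v:.6g}" for v in flat[i:i + 9])
                     for i in range(0, flat.size, 9))
    Path(path).write_text("\n".join(lines) + "\n")


def save_state(state: FlowState, path):
    """Checkpoint a flow state to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["t"] = state.t
        for a, arr in state.comps.items():
            f.create_dataset(f"u{a}", data=arr)
        f.create_dataset("p", data=state.p)


def load_state(path) -> FlowState:
    import h5py

    with h5py.File(path, "r") as f:
        comps = {a: f[f"u{a}"][...] for a in range(3) if f"u{a}" in f}
        return FlowState(t=float(f.attrs["t"]), comps=comps, p=f["p"][...])


def save_config(config, path):
    from .pipeline import ScenarioConfig

    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def load_config(path):
    from .pipeline import ScenarioConfig

    return ScenarioConfig.from_dict(yaml.safe_load(Path(path).read_text()))
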