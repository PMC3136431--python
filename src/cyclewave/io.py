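"""Run artifacts: HDF5 kymographs, CSV division records, VTK snapshots,
trajectory CSVs and archived resolved configs."""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .config import SimConfig, save_config
from .diagnostics import DivisionRecord
from .kinetics import SPECIES, Trajectory
from .meshes import EmbryoMesh
from .solver1d import Kymograph

__all__ = ["write_kymograph", "read_kymograph", "write_divisions",
           "write_trajectory_csv", "write_vtk", "archive_run"]


def write_kymograph(path: str | Path, kymo: Kymograph,
                    metadata: dict | None = None) -> None:
    """HDF5 layout: /t (min), /x_mm, /species/<name> (time x space)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("t", data=kymo.t)
        f.create_dataset("x_mm", data=kymo.x_mm)
        grp = f.create_group("species")
        for name, arr in kymo.data.items():
            grp.create_dataset(name, data=arr, compression="gzip")
        if metadata:
            f.attrs["metadata"] = json.dumps(metadata)


def read_kymograph(path: str | Path) -> tuple[Kymograph, dict]:
    with h5py.File(path, "r") as f:
        kymo = Kymograph(f["t"][:], f["x_mm"][:],
                         {k: v[:] for k, v in f["species"].items()})
        meta = json.loads(f.attrs.get("metadata", "{}"))
    return kymo, meta


def write_divisions(path: str | Path, record: DivisionRecord) -> None:
    """Long-format CSV: position, event index, division time."""
    rows = [(float(record.positions[j]), k, float(tk))
            for j, tj in enumerate(record.times)
            for k, tk in enumerate(tj)]
    pd.DataFrame(rows, columns=["position", "event", "time_min"]).to_csv(
        path, index=False)


def write_trajectory_csv(path: str | Path, traj: Trajectory) -> None:
    df = pd.DataFrame({"time_min": traj.t})
    for i, name in enumerate(SPECIES):
        df[name] = traj.y[i]
    df.to_csv(path, index=False)


def write_vtk(path: str | Path, mesh: EmbryoMesh,
              vertex_data: dict[str, np.ndarray] | None = None) -> None:
    """Legacy ASCII VTK unstructured grid (triangles or tetrahedra), with
    optional per-vertex scalar fields — enough for ParaView inspection."""
    v = mesh.vertices
    if v.shape[1] == 2:  # axisym section: embed in 3D at z = 0
        v = np.column_stack([v, np.zeros(len(v))])
    cell_type = 5 if mesh.elements.shape[1] == 3 else 10
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\ncyclewave snapshot\nASCII\n"
                "DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {len(v)} float\n")
        np.savetxt(f, v, fmt="%.6g")
        ne, nk = mesh.elements.shape
        f.write(f"CELLS {ne} {ne * (nk + 1)}\n")
        np.savetxt(f, np.column_stack([np.full(ne, nk), mesh.elements]),
                   fmt="%d")
        f.write(f"CELL_TYPES {ne}\n")
        np.savetxt(f, np.full(ne, cell_type), fmt="%d")
        f.write(f"CELL_DATA {ne}\nSCALARS cell_label int 1\n"
                "LOOKUP_TABLE default\n")
        np.savetxt(f, mesh.cell_labels, fmt="%d")
        if vertex_data:
            f.write(f"POINT_DATA {len(v)}\n")
            for name, arr in vertex_data.items():
                f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                np.savetxt(f, np.asarray(arr), fmt="%.6g")


def archive_run(out_dir: str | Path, config: SimConfig,
                extra: dict | None = None) -> Path:
    """Write the exact resolved config (plus free-form metadata) beside
    the run outputs; returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(config, out / "config.resolved.yaml")
    if extra:
        with open(out / "run_metadata.json", "w") as fh:
            json.dump(extra, fh, indent=2, default=str)
    return out
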