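"""Snapshot, checkpoint and log output.

VTK snapshots are legacy-ASCII unstructured point clouds with the per-point
arrays a viewer needs to color cell types and fields; HDF5 checkpoints hold
the complete particle state plus clocks and RNG state for exact restart.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .points import CellType, ParticleState

__all__ = ["write_vtk", "write_checkpoint", "read_checkpoint",
           "census_frame", "metrics_frame"]

#: integer code → name legend written into every VTK header
CELL_TYPE_LEGEND = {int(t): t.name.lower() for t in CellType}


def write_vtk(points: ParticleState, path) -> None:
    """Write a legacy-ASCII VTK point cloud with per-point data arrays."""
    n = points.n
    legend = ", ".join(f"{k}={v}" for k, v in CELL_TYPE_LEGEND.items())
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"ossiforge snapshot; cell_type codes: {legend}\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {n} double\n")
        np.savetxt(fh, points.x, fmt="%.6g")
        fh.write(f"CELLS {n} {2 * n}\n")
        np.savetxt(fh, np.column_stack([np.ones(n, dtype=int),
                                        np.arange(n)]), fmt="%d")
        fh.write(f"CELL_TYPES {n}\n")
        np.savetxt(fh, np.ones(n, dtype=int), fmt="%d")  # VTK_VERTEX
        fh.write(f"POINT_DATA {n}\n")
        for name, arr, fmt in (
                ("cell_type", points.cell_type, "%d"),
                ("volume", points.V, "%.6g"),
                ("youngs_modulus", points.E, "%.6g"),
                ("C_Ihh", points.C_ihh, "%.6g"),
                ("C_PTHrP", points.C_pthrp, "%.6g"),
                ("t_H", points.t_H, "%.6g")):
            kind = "int" if fmt == "%d" else "double"
            fh.write(f"SCALARS {name} {kind} 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr, fmt=fmt)


def write_checkpoint(sim, path) -> None:
    """Full-state HDF5 checkpoint of a simulation driver."""
    p = sim.points
    with h5py.File(path, "w") as fh:
        g = fh.create_group("points")
        for name in (("x", "F", "Fg", "Fg0", "n_s")
                     + ParticleState._SCALARS + ParticleState._INTS
                     + ParticleState._BOOLS):
            g.create_dataset(name, data=getattr(p, name))
        fh.attrs["day"] = sim.day
        fh.attrs["t_soc"] = -1.0 if sim.t_soc is None else sim.t_soc
        fh.attrs["rng_state"] = json.dumps(
            sim.rng.bit_generator.state)
        for name in ("poc_ids", "soc_ids", "resting_ids"):
            fh.create_dataset(name, data=np.asarray(getattr(sim, name),
                                                    dtype=int))
        c = fh.create_group("field")
        c.create_dataset("C_ihh", data=sim.field.C_ihh)
        c.create_dataset("C_pthrp", data=sim.field.C_pthrp)
        c.attrs["shape"] = sim.field.shape
        c.attrs["h"] = sim.field.h


def read_checkpoint(path):
    """Load a checkpoint into a plain dict (points + clocks + field)."""
    out = {}
    with h5py.File(path, "r") as fh:
        g = fh["points"]
        x = g["x"][()]
        p = ParticleState(x, g["V"][()])
        for name in (("F", "Fg", "Fg0", "n_s") + ParticleState._SCALARS
                     + ParticleState._INTS + ParticleState._BOOLS):
            setattr(p, name, g[name][()])
        out["points"] = p
        out["day"] = float(fh.attrs["day"])
        t_soc = float(fh.attrs["t_soc"])
        out["t_soc"] = None if t_soc < 0 else t_soc
        out["rng_state"] = json.loads(fh.attrs["rng_state"])
        for name in ("poc_ids", "soc_ids", "resting_ids"):
            out[name] = fh[name][()]
        out["field"] = {"C_ihh": fh["field/C_ihh"][()],
                        "C_pthrp": fh["field/C_pthrp"][()],
                        "shape": tuple(fh["field"].attrs["shape"]),
                        "h": float(fh["field"].attrs["h"])}
    return out


def census_frame(census) -> pd.DataFrame:
    """Day × cell-type count table from a driver's census log."""
    rows = []
    for day, counts in census:
        row = {"day": day}
        row.update({CellType(t).name.lower(): c for t, c in counts.items()})
        rows.append(row)
    return pd.DataFrame(rows).fillna(0)


def metrics_frame(metrics) -> pd.DataFrame:
    """Zone-metrics table (μm) from a driver's metrics log."""
    return pd.DataFrame([{
        "day": m.day, "proliferative_um": m.proliferative,
        "prehypertrophic_um": m.prehypertrophic,
        "hypertrophic_um": m.hypertrophic, "combined_um": m.combined,
        "subarticular_um": m.subarticular_um} for m in metrics])
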