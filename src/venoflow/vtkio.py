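"""Reading and writing meshes and fields.

Surface meshes travel as STL (via :mod:`trimesh`) or legacy ASCII VTK
polydata; volume meshes as legacy ASCII VTK unstructured grids (cell type 10,
linear tetrahedra).  Vector point-data arrays are named ``velocity`` or
``wss`` with the phase index encoded as a ``_t###`` suffix; the surface
boundary labels are stored as a cell-data scalar named ``boundary_id``.

The legacy VTK ASCII format is a line-oriented text format; the writer and
reader here cover exactly the subset this package produces.
"""
from __future__ import annotations

import re
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .geometry import TetVolumeMesh, TriSurfaceMesh

__all__ = [
    "write_surface_vtk",
    "read_surface_vtk",
    "write_volume_vtk",
    "read_volume_vtk",
    "write_surface_stl",
    "read_surface_stl",
    "write_waveform_csv",
    "read_waveform_csv",
]


def _fmt_points(points: np.ndarray) -> str:
    return "\n".join(" ".join(repr(float(v)) for v in row) for row in points)


def _write_point_data(fh, point_data: Dict[str, np.ndarray], n_points: int) -> None:
    if not point_data:
        return
    fh.write(f"POINT_DATA {n_points}\n")
    for name, arr in point_data.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 2 and arr.shape[1] == 3:
            fh.write(f"VECTORS {name} double\n")
            fh.write(_fmt_points(arr) + "\n")
        elif arr.ndim == 1:
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(repr(float(v)) for v in arr) + "\n")
        else:
            raise ValueError(f"unsupported point-data shape for {name}: {arr.shape}")


def write_surface_vtk(
    path, mesh: TriSurfaceMesh, point_data: Optional[Dict[str, np.ndarray]] = None
) -> None:
    """Write a triangle surface as legacy ASCII VTK polydata."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nvenoflow surface\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        fh.write(_fmt_points(mesh.nodes) + "\n")
        m = mesh.n_triangles
        fh.write(f"POLYGONS {m} {4 * m}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        fh.write(f"CELL_DATA {m}\n")
        fh.write("SCALARS boundary_id int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(int(b)) for b in mesh.boundary_id) + "\n")
        _write_point_data(fh, point_data or {}, mesh.n_nodes)


def write_volume_vtk(
    path, mesh: TetVolumeMesh, point_data: Optional[Dict[str, np.ndarray]] = None
) -> None:
    """Write a tet mesh as legacy ASCII VTK unstructured grid."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nvenoflow volume\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        fh.write(_fmt_points(mesh.nodes) + "\n")
        m = mesh.n_tets
        fh.write(f"CELLS {m} {5 * m}\n")
        for t in mesh.tets:
            fh.write(f"4 {t[0]} {t[1]} {t[2]} {t[3]}\n")
        fh.write(f"CELL_TYPES {m}\n")
        fh.write("\n".join(["10"] * m) + "\n")
        _write_point_data(fh, point_data or {}, mesh.n_nodes)


def _tokenize(path) -> list:
    with open(path) as fh:
        text = fh.read()
    return text.split()


def _read_blocks(tokens):
    """Walk the token stream, yielding (keyword, payload) sections."""
    i = 0
    n = len(tokens)
    out = {}
    point_data: Dict[str, np.ndarray] = {}
    cell_data: Dict[str, np.ndarray] = {}
    n_points = 0
    while i < n:
        tok = tokens[i].upper()
        if tok == "POINTS":
            n_points = int(tokens[i + 1])
            vals = np.array(tokens[i + 3 : i + 3 + 3 * n_points], dtype=float)
            out["points"] = vals.reshape(n_points, 3)
            i += 3 + 3 * n_points
        elif tok in ("POLYGONS", "CELLS"):
            n_cells = int(tokens[i + 1])
            size = int(tokens[i + 2])
            vals = np.array(tokens[i + 3 : i + 3 + size], dtype=np.int64)
            cells = []
            j = 0
            for _ in range(n_cells):
                k = vals[j]
                cells.append(vals[j + 1 : j + 1 + k])
                j += 1 + k
            out["cells"] = np.asarray(cells)
            i += 3 + size
        elif tok == "CELL_TYPES":
            m = int(tokens[i + 1])
            i += 2 + m
        elif tok in ("POINT_DATA", "CELL_DATA"):
            count = int(tokens[i + 1])
            target = point_data if tok == "POINT_DATA" else cell_data
            i += 2
            while i < n and tokens[i].upper() in ("SCALARS", "VECTORS"):
                kind = tokens[i].upper()
                name = tokens[i + 1]
                if kind == "SCALARS":
                    i += 4  # SCALARS name type ncomp
                    if tokens[i].upper() == "LOOKUP_TABLE":
                        i += 2
                    target[name] = np.array(tokens[i : i + count], dtype=float)
                    i += count
                else:
                    i += 3
                    target[name] = np.array(
                        tokens[i : i + 3 * count], dtype=float
                    ).reshape(count, 3)
                    i += 3 * count
        else:
            i += 1
    out["point_data"] = point_data
    out["cell_data"] = cell_data
    return out


def read_surface_vtk(path) -> Tuple[TriSurfaceMesh, Dict[str, np.ndarray]]:
    blocks = _read_blocks(_tokenize(path))
    bid = blocks["cell_data"].get("boundary_id")
    mesh = TriSurfaceMesh(
        nodes=blocks["points"],
        triangles=np.asarray(blocks["cells"], dtype=np.int64),
        boundary_id=None if bid is None else bid.astype(np.int64),
    )
    return mesh, blocks["point_data"]


def read_volume_vtk(path) -> Tuple[TetVolumeMesh, Dict[str, np.ndarray]]:
    blocks = _read_blocks(_tokenize(path))
    mesh = TetVolumeMesh(
        nodes=blocks["points"], tets=np.asarray(blocks["cells"], dtype=np.int64)
    )
    return mesh, blocks["point_data"]


def write_surface_stl(path, mesh: TriSurfaceMesh, ascii_format: bool = True) -> None:
    import trimesh

    tm = trimesh.Trimesh(vertices=mesh.nodes, faces=mesh.triangles, process=False)
    if ascii_format:
        with open(path, "w") as fh:
            fh.write(trimesh.exchange.stl.export_stl_ascii(tm))
    else:
        tm.export(path, file_type="stl")


def read_surface_stl(path) -> TriSurfaceMesh:
    import trimesh

    tm = trimesh.load(path, file_type="stl", process=True)
    return TriSurfaceMesh(nodes=np.asarray(tm.vertices), triangles=np.asarray(tm.faces))


# ---------------------------------------------------------------------------
# waveform CSV
# ---------------------------------------------------------------------------

def write_waveform_csv(path, waveform) -> None:
    """Two-column CSV ``time_s,flow_ml_s``; the period is recorded in a
    ``# period_s=`` comment line so round trips are lossless."""
    with open(path, "w") as fh:
        fh.write(f"# period_s={waveform.period!r}\n")
        pd.DataFrame(
            {"time_s": waveform.times, "flow_ml_s": waveform.flows}
        ).to_csv(fh, index=False)


def read_waveform_csv(path, period: Optional[float] = None):
    """Read a waveform CSV.  If no ``# period_s=`` comment and no explicit
    period is given, the period is inferred from the (uniform) sample spacing.
    """
    from .waveforms import Waveform

    with open(path) as fh:
        first = fh.readline()
        m = re.match(r"#\s*period_s\s*=\s*([0-9.eE+-]+)", first)
        if m:
            period = float(m.group(1))
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    times = df["time_s"].to_numpy(dtype=float)
    flows = df["flow_ml_s"].to_numpy(dtype=float)
    if period is None:
        dt = np.diff(times)
        if dt.size and np.allclose(dt, dt[0], rtol=1e-6):
            period = float(times[-1] + dt[0] - times[0])
        else:
            raise ValueError(
                "cannot infer the period from non-uniform samples; pass period="
            )
    return Waveform(times=times, flows=flows, period=period)
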