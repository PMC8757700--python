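"""File I/O: material-curve manifests (CSV + YAML/JSON), VTU field export,
HDF5 mesh interchange and history tables.

The VTU writer emits plain ASCII XML unstructured-grid files (hexahedron
cells with point/cell data), which ParaView and compatible tools read
directly.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .fem import HexMesh
from .material import CurveFamily, UniaxialCurve

__all__ = [
    "read_curve_family",
    "write_curve_family",
    "write_vtu",
    "write_mesh_h5",
    "read_mesh_h5",
]


# ---------------------------------------------------------------------------
# material curves
# ---------------------------------------------------------------------------

def _read_curve_csv(path: Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    if "strain" not in cols or "stress" not in cols:
        raise ValueError(f"{path}: curve CSV needs 'strain' and 'stress' columns")
    return df[cols["strain"]].to_numpy(float), df[cols["stress"]].to_numpy(float)


def read_curve_family(manifest_path: str | os.PathLike) -> CurveFamily:
    """Load a curve family from a YAML/JSON manifest.

    Manifest schema::

        curves:
          - file: curve_T25_r0.01.csv      # CSV with header strain,stress
            temperature: 25.0              # °C
            strain_rate: 0.01              # 1/s
            unloading_file: unl_T25.csv    # optional
    """
    manifest_path = Path(manifest_path)
    text = manifest_path.read_text()
    spec = (
        json.loads(text) if manifest_path.suffix == ".json" else yaml.safe_load(text)
    )
    curves = []
    base = manifest_path.parent
    for entry in spec["curves"]:
        e, s = _read_curve_csv(base / entry["file"])
        ue = uv = None
        if entry.get("unloading_file"):
            ue, uv = _read_curve_csv(base / entry["unloading_file"])
        curves.append(
            UniaxialCurve(
                e, s,
                temperature=float(entry["temperature"]),
                strain_rate=float(entry["strain_rate"]),
                unloading_strains=ue,
                unloading_stresses=uv,
            )
        )
    return CurveFamily(curves)


def write_curve_family(family: CurveFamily, out_dir: str | os.PathLike) -> Path:
    """Write each curve as CSV plus a YAML manifest; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for c in family.curves:
        tag = f"T{c.temperature:g}_r{c.strain_rate:g}"
        fname = f"curve_{tag}.csv"
        pd.DataFrame({"strain": c.strains, "stress": c.stresses}).to_csv(
            out / fname, index=False
        )
        entry = {
            "file": fname,
            "temperature": float(c.temperature),
            "strain_rate": float(c.strain_rate),
        }
        if c.has_unloading:
            ufname = f"unloading_{tag}.csv"
            pd.DataFrame(
                {"strain": c.unloading_strains, "stress": c.unloading_stresses}
            ).to_csv(out / ufname, index=False)
            entry["unloading_file"] = ufname
        entries.append(entry)
    manifest = out / "manifest.yaml"
    manifest.write_text(yaml.safe_dump({"curves": entries}, sort_keys=False))
    return manifest


# ---------------------------------------------------------------------------
# VTU export
# ---------------------------------------------------------------------------

def _ascii(arr: np.ndarray) -> str:
    return "\n".join(" ".join(f"{v:.9g}" for v in np.atleast_1d(row)) for row in arr)


def write_vtu(
    path: str | os.PathLike,
    mesh: HexMesh,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
    displacements: np.ndarray | None = None,
) -> Path:
    """Write the mesh (optionally deformed) with fields as ASCII VTU."""
    path = Path(path)
    nodes = mesh.nodes if displacements is None else mesh.nodes + displacements
    n_pts, n_cells = mesh.n_nodes, mesh.n_elements
    offsets = 8 * np.arange(1, n_cells + 1)

    def data_arrays(data: dict[str, np.ndarray] | None) -> str:
        if not data:
            return ""
        chunks = []
        for name, arr in data.items():
            arr = np.asarray(arr, dtype=float)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            chunks.append(
                f'<DataArray type="Float64" Name="{name}" '
                f'NumberOfComponents="{ncomp}" format="ascii">\n'
                f"{_ascii(arr)}\n</DataArray>"
            )
        return "\n".join(chunks)

    xml = f"""<?xml version="1.0"?>
<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">
<UnstructuredGrid>
<Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">
<Points>
<DataArray type="Float64" NumberOfComponents="3" format="ascii">
{_ascii(nodes)}
</DataArray>
</Points>
<Cells>
<DataArray type="Int64" Name="connectivity" format="ascii">
{_ascii(mesh.elements)}
</DataArray>
<DataArray type="Int64" Name="offsets" format="ascii">
{_ascii(offsets)}
</DataArray>
<DataArray type="UInt8" Name="types" format="ascii">
{_ascii(np.full(n_cells, 12))}
</DataArray>
</Cells>
<PointData>
{data_arrays(point_data)}
</PointData>
<CellData>
{data_arrays(cell_data)}
</CellData>
</Piece>
</UnstructuredGrid>
</VTKFile>
"""
    path.write_text(xml)
    return path


# ---------------------------------------------------------------------------
# HDF5 mesh interchange
# ---------------------------------------------------------------------------

def write_mesh_h5(path: str | os.PathLike, mesh: HexMesh) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("nodes", data=mesh.nodes)
        f.create_dataset("elements", data=mesh.elements)
        ns = f.create_group("node_sets")
        for k, v in mesh.node_sets.items():
            ns.create_dataset(k, data=np.asarray(v, dtype=np.int64))
        fs = f.create_group("face_sets")
        for k, v in mesh.face_sets.items():
            fs.create_dataset(k, data=np.asarray(v, dtype=np.int64))
    return path


def read_mesh_h5(path: str | os.PathLike) -> HexMesh:
    with h5py.File(path, "r") as f:
        mesh = HexMesh(
            f["nodes"][()],
            f["elements"][()],
            {k: v[()] for k, v in f["node_sets"].items()},
            {k: v[()] for k, v in f["face_sets"].items()},
        )
    return mesh
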