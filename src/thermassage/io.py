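"""Field export: legacy VTK structured points and compressed array containers."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = [
    "write_vtk_structured_points",
    "write_field_npz",
    "read_field_npz",
    "write_json",
]


def write_vtk_structured_points(
    path: str | Path,
    values: np.ndarray,
    spacing_mm: float,
    scalar_name: str = "temperature_C",
    origin_mm: tuple[float, float, float] | None = None,
) -> Path:
    """Write a 3D scalar grid as a legacy ASCII VTK structured-points file.

    The array is indexed (x, y, z); VTK expects x varying fastest, so values
    are emitted in Fortran order. Integer arrays are written as int scalars
    (tissue labels), floats as double.
    """
    path = Path(path)
    values = np.asarray(values)
    if values.ndim != 3:
        raise ValueError("expected a 3D array")
    nx, ny, nz = values.shape
    if origin_mm is None:
        origin_mm = (-nx * spacing_mm / 2.0 + spacing_mm / 2.0,
                     -ny * spacing_mm / 2.0 + spacing_mm / 2.0,
                     spacing_mm / 2.0)
    is_int = np.issubdtype(values.dtype, np.integer)
    vtk_type = "int" if is_int else "double"
    flat = values.ravel(order="F")
    with path.open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{scalar_name} on a voxel grid (spacing {spacing_mm} mm)\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {origin_mm[0]} {origin_mm[1]} {origin_mm[2]}\n")
        fh.write(f"SPACING {spacing_mm} {spacing_mm} {spacing_mm}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        fh.write(f"SCALARS {scalar_name} {vtk_type} 1\nLOOKUP_TABLE default\n")
        fmt = "%d" if is_int else "%.6g"
        np.savetxt(fh, flat.reshape(-1, 1), fmt=fmt)
    return path


def write_field_npz(path: str | Path, values: np.ndarray, spacing_mm: float,
                    **metadata) -> Path:
    """Compressed array container with spacing and JSON-able metadata."""
    path = Path(path)
    np.savez_compressed(
        path,
        values=values,
        spacing_mm=np.float64(spacing_mm),
        metadata=json.dumps(metadata, sort_keys=True),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def read_field_npz(path: str | Path) -> tuple[np.ndarray, float, dict]:
    with np.load(path) as npz:
        values = npz["values"]
        spacing = float(npz["spacing_mm"])
        metadata = json.loads(str(npz["metadata"]))
    return values, spacing, metadata


def write_json(path: str | Path, obj) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path
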