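"""Plain-text output: legacy-VTK writers and CSV time series."""

from __future__ import annotations

import csv

import numpy as np

from .grid import Grid2D

__all__ = ["write_vtk_structured", "write_vtk_polylines", "write_timeseries_csv"]


def write_vtk_structured(path, grid: Grid2D, fields: dict) -> None:
    """Legacy-VTK ASCII structured-points file with nodal scalar fields."""
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nnanotherm field output\nASCII\n")
        f.write("DATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {grid.nx + 1} {grid.ny + 1} 1\n")
        f.write("ORIGIN 0 0 0\n")
        f.write(f"SPACING {grid.hx:.9g} {grid.hy:.9g} 1\n")
        f.write(f"POINT_DATA {grid.n_nodes}\n")
        for name, data in fields.items():
            f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(f, np.asarray(data).ravel(), fmt="%.9g")


def write_vtk_polylines(path, nodes: np.ndarray, segments: np.ndarray,
                        cell_fields: dict | None = None) -> None:
    """Legacy-VTK ASCII polydata of vessel segments with per-segment data."""
    nodes = np.asarray(nodes, float)
    segments = np.asarray(segments, int)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nnanotherm vessel network\nASCII\n")
        f.write("DATASET POLYDATA\n")
        f.write(f"POINTS {len(nodes)} double\n")
        for x, y in nodes:
            f.write(f"{x:.9g} {y:.9g} 0\n")
        f.write(f"LINES {len(segments)} {3 * len(segments)}\n")
        for a, b in segments:
            f.write(f"2 {a} {b}\n")
        if cell_fields:
            f.write(f"CELL_DATA {len(segments)}\n")
            for name, data in cell_fields.items():
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(f, np.asarray(data, float).ravel(), fmt="%.9g")


def write_timeseries_csv(path, columns: dict) -> None:
    """Write named 1D arrays of equal length as CSV columns."""
    keys = list(columns)
    rows = zip(*[np.asarray(columns[k]).tolist() for k in keys])
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(keys)
        w.writerows(rows)
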