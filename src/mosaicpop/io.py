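"""Plain-text landscape I/O: ESRI ASCII grid + CSV patch attribute table.

The grid file is a standard ESRI ASCII raster of integer patch
identifiers; the table is a CSV with header ``id,type_code,barrier``.
Areas and centroids are always recomputed from the grid on read, never
trusted from file, so a write -> read round trip reproduces the landscape
exactly.
"""

from __future__ import annotations

import csv

import numpy as np
import pandas as pd

from .landscape import BARRIER_TYPES, Landscape, _areas_from_grid, _centroids_from_grid

__all__ = ["read_landscape", "write_landscape"]

_NODATA = -9999
_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def write_landscape(landscape: Landscape, grid_path, table_path) -> None:
    """Write the patch-ID raster (ESRI ASCII) and attribute table (CSV)."""
    grid = landscape.grid
    nrows, ncols = grid.shape
    with open(grid_path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write(f"cellsize {landscape.cell_size!r}\n")
        fh.write(f"NODATA_value {_NODATA}\n")
        for row in grid:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")
    with open(table_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "type_code", "barrier"])
        for pid, rec in landscape.patches.iterrows():
            w.writerow([int(pid), rec["type_code"], int(bool(rec["barrier"]))])


def read_landscape(grid_path, table_path) -> Landscape:
    """Read a landscape from an ESRI ASCII grid plus a CSV patch table.

    Raises ValueError when the grid references an identifier absent from
    the table (the offending identifiers are named) or when either header
    is malformed.
    """
    header: dict[str, float] = {}
    rows: list[list[int]] = []
    with open(grid_path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"malformed ESRI ASCII header in {grid_path}: missing {key}")
    for line in lines[i:]:
        if line.strip():
            rows.append([int(v) for v in line.split()])
    grid = np.asarray(rows, dtype=np.int64)
    if grid.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"grid body {grid.shape} disagrees with header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )

    tab = pd.read_csv(table_path)
    if list(tab.columns[:3]) != ["id", "type_code", "barrier"]:
        raise ValueError(
            f"malformed patch table header in {table_path}: "
            f"expected id,type_code,barrier got {list(tab.columns)}"
        )
    tab["barrier"] = tab["barrier"].astype(bool)
    tab = tab.set_index("id").sort_index()

    ids_grid = np.unique(grid)
    missing = np.setdiff1d(ids_grid, tab.index.to_numpy())
    if missing.size:
        raise ValueError(
            f"grid identifiers missing from patch table: {missing.tolist()}"
        )
    tab = tab.loc[np.isin(tab.index.to_numpy(), ids_grid)]
    bad = tab[tab["barrier"] != tab["type_code"].isin(BARRIER_TYPES)]
    if len(bad):
        raise ValueError(f"barrier flag inconsistent with type for ids {bad.index.tolist()}")

    ids = tab.index.to_numpy()
    tab["area_cells"] = _areas_from_grid(grid, ids)
    cent = _centroids_from_grid(grid, ids)
    tab["centroid_row"] = cent[:, 0]
    tab["centroid_col"] = cent[:, 1]
    return Landscape(grid, tab, cell_size=float(header["cellsize"]))
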