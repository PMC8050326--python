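"""Readers and writers: point CSV tables, ESRI ASCII grids, JSON results.

CSV dialect is fixed (comma separator, period decimal) regardless of
locale. Floats are written at 10 significant digits so a write/read
round trip is an identity at that precision.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import PointDataset, RasterGrid

_FLOAT_FMT = "%.10g"


def write_point_csv(dataset: PointDataset, path: str | Path) -> None:
    dataset.frame.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_point_csv(
    path: str | Path,
    grid_spacing: float | None = None,
    strict: bool = True,
) -> PointDataset:
    """Read a point table; requires ``x`` and ``y`` columns, all numeric.

    ``strict`` makes duplicate coordinates an error (listing the offending
    row pairs); otherwise they are tolerated until an operation that
    cannot handle them (kriging) rejects them.
    """
    frame = pd.read_csv(path)
    for col in ("x", "y"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    for col in frame.columns:
        if not pd.api.types.is_numeric_dtype(frame[col]):
            raise ValueError(f"{path}: non-numeric values in column {col!r}")
    ds = PointDataset(frame, grid_spacing=grid_spacing)
    if strict:
        ds.check_unique_coordinates()
    return ds


def write_ascii_grid(raster: RasterGrid, path: str | Path) -> None:
    """ESRI ASCII grid: 6-line header then rows north to south."""
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.n_cols}\n")
        fh.write(f"nrows {raster.n_rows}\n")
        fh.write(f"xllcorner {_FLOAT_FMT % raster.origin[0]}\n")
        fh.write(f"yllcorner {_FLOAT_FMT % raster.origin[1]}\n")
        fh.write(f"cellsize {_FLOAT_FMT % raster.cell_size}\n")
        fh.write(f"NODATA_value {_FLOAT_FMT % raster.nodata}\n")
        for row in raster.values:
            fh.write(" ".join(_FLOAT_FMT % v for v in row) + "\n")


def read_ascii_grid(path: str | Path) -> RasterGrid:
    with open(path) as fh:
        lines = fh.read().splitlines()
    header = {}
    expected = ["ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"]
    for i, key in enumerate(expected):
        if i >= len(lines):
            raise ValueError(f"{path}: truncated header at line {i + 1}")
        parts = lines[i].split()
        if len(parts) != 2 or parts[0].lower() != key:
            raise ValueError(f"{path}: malformed header at line {i + 1}: {lines[i]!r}")
        header[key] = float(parts[1])
    n_cols, n_rows = int(header["ncols"]), int(header["nrows"])
    if header["cellsize"] <= 0:
        raise ValueError(f"{path}: cellsize must be positive (header line 5)")
    body = lines[6 : 6 + n_rows]
    if len(body) < n_rows:
        raise ValueError(f"{path}: expected {n_rows} data rows, found {len(body)}")
    values = np.array([[float(v) for v in row.split()] for row in body])
    if values.shape != (n_rows, n_cols):
        raise ValueError(f"{path}: data shape {values.shape} != ({n_rows}, {n_cols})")
    return RasterGrid(
        origin=(header["xllcorner"], header["yllcorner"]),
        cell_size=header["cellsize"],
        values=values,
        nodata=header["nodata_value"],
    )


class _ResultEncoder(json.JSONEncoder):
    def default(self, o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        if isinstance(o, pd.DataFrame):
            return {"index": o.index.tolist(), "columns": o.columns.tolist(),
                    "data": o.to_numpy().tolist()}
        return super().default(o)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_ResultEncoder)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
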