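"""Core in-memory containers: georeferenced point tables and raster grids.

Coordinates are planar metres with the origin at the survey's southwest
corner. A :class:`PointDataset` is a thin, validated wrapper around a
:class:`pandas.DataFrame` with ``x``/``y`` columns plus one numeric column
per soil attribute; a :class:`RasterGrid` carries an interpolated map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COORD_COLUMNS = ("x", "y")


class DuplicateCoordinateError(ValueError):
    """Raised when two rows share the same (x, y) location."""

    def __init__(self, pairs: list[tuple[int, int]]):
        self.pairs = pairs
        super().__init__(
            "duplicate sample coordinates at row pairs: "
            + ", ".join(f"{i}~{j}" for i, j in pairs)
        )


def _duplicate_pairs(coords: np.ndarray) -> list[tuple[int, int]]:
    seen: dict[tuple[float, float], int] = {}
    pairs = []
    for i, (x, y) in enumerate(coords):
        key = (float(x), float(y))
        if key in seen:
            pairs.append((seen[key], i))
        else:
            seen[key] = i
    return pairs


@dataclass
class PointDataset:
    """Georeferenced sample table.

    Parameters
    ----------
    frame
        Table with ``x`` and ``y`` coordinate columns (metres) and one
        numeric column per attribute.
    grid_spacing
        Declared minimum spacing of the sampling design, if regular.
    """

    frame: pd.DataFrame
    grid_spacing: float | None = None

    def __post_init__(self) -> None:
        missing = [c for c in COORD_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"point table lacks coordinate column(s): {missing}")
        self.frame = self.frame.reset_index(drop=True)
        for col in self.frame.columns:
            if not pd.api.types.is_numeric_dtype(self.frame[col]):
                raise ValueError(f"non-numeric column in point table: {col!r}")

    # -- accessors ---------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def coords(self) -> np.ndarray:
        return self.frame.loc[:, list(COORD_COLUMNS)].to_numpy(dtype=float)

    @property
    def attributes(self) -> list[str]:
        return [c for c in self.frame.columns if c not in COORD_COLUMNS]

    def values(self, attribute: str) -> np.ndarray:
        if attribute not in self.frame.columns or attribute in COORD_COLUMNS:
            raise KeyError(f"unknown attribute {attribute!r}; have {self.attributes}")
        vals = self.frame[attribute].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            bad = np.flatnonzero(~np.isfinite(vals)).tolist()
            raise ValueError(f"attribute {attribute!r} has non-finite values at rows {bad}")
        return vals

    def check_unique_coordinates(self) -> None:
        pairs = _duplicate_pairs(self.coords)
        if pairs:
            raise DuplicateCoordinateError(pairs)

    def with_column(self, name: str, values: np.ndarray) -> "PointDataset":
        frame = self.frame.copy()
        frame[name] = np.asarray(values, dtype=float)
        return PointDataset(frame, self.grid_spacing)

    def max_pairwise_distance(self) -> float:
        from scipy.spatial.distance import pdist

        return float(pdist(self.coords).max())


@dataclass
class RasterGrid:
    """Regular raster, row 0 = northernmost row (row-major north to south).

    ``origin`` is the lower-left (southwest) corner of the lower-left cell,
    following the ESRI ASCII grid convention.
    """

    origin: tuple[float, float]
    cell_size: float
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D matrix")
        if self.cell_size <= 0:
            raise ValueError(f"cell size must be positive, got {self.cell_size}")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> np.ndarray:
        """(n_rows*n_cols, 2) x/y centres, in storage (row-major N->S) order."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = y0 + (self.n_rows - 0.5 - np.arange(self.n_rows)) * self.cell_size
        xx, yy = np.meshgrid(xs, ys)
        return np.column_stack([xx.ravel(), yy.ravel()])

    def finite_values(self) -> np.ndarray:
        vals = self.values[self.values != self.nodata]
        return vals[np.isfinite(vals)]

    @classmethod
    def from_extent(
        cls,
        xmin: float,
        ymin: float,
        xmax: float,
        ymax: float,
        cell_size: float,
        nodata: float = -9999.0,
    ) -> "RasterGrid":
        """Blank raster whose first cell centre coincides with (xmin, ymin).

        Aligning centres with the data lattice keeps kriged maps exact at
        sample locations.
        """
        n_cols = int(np.floor((xmax - xmin) / cell_size)) + 1
        n_rows = int(np.floor((ymax - ymin) / cell_size)) + 1
        origin = (xmin - cell_size / 2.0, ymin - cell_size / 2.0)
        values = np.full((n_rows, n_cols), nodata, dtype=float)
        return cls(origin=origin, cell_size=cell_size, values=values, nodata=nodata)


def regular_grid_coords(extent: float, spacing: float) -> np.ndarray:
    """Coordinates of a square regular grid: (0..extent) x (0..extent).

    ``extent`` must be an integer multiple of ``spacing``; the survey design
    emulated throughout is 90 m x 90 m at 10 m spacing = 100 points.
    """
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    ratio = extent / spacing
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"extent {extent} is not a multiple of spacing {spacing}")
    ticks = np.arange(round(ratio) + 1) * spacing
    xx, yy = np.meshgrid(ticks, ticks)
    return np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
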