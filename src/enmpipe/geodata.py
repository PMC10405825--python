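"""Raster and occurrence I/O, grid geometry, and occurrence cleaning.

Everything downstream runs on a single geographic (lon/lat, WGS84) grid.
A :class:`Grid` is one single-band raster; an :class:`EnvStack` is an
ordered, aligned collection of them (the environmental predictors); an
:class:`OccurrenceSet` is a set of presence coordinates in decimal degrees.

Supported raster dialects are ESRI ASCII grids (``.asc``/``.txt``) and
single-band GeoTIFF (``.tif``/``.tiff``), selected by file extension.
Row 0 is always the northernmost row; cells are half-open
``[x, x + cell_size)`` squares; conversions between indices and
coordinates use cell centers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Mean Earth radius in km (IUGG), used for spherical cell areas.
EARTH_RADIUS_KM = 6371.0088

_ASCII_HEADER_KEYS = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}


class RasterFormatError(ValueError):
    """Raised when a raster file cannot be parsed."""


class GridAlignmentError(ValueError):
    """Raised when two grids that must share geometry do not."""


@dataclass
class Grid:
    """A georeferenced single-band raster on a geographic lat/lon lattice.

    Attributes
    ----------
    n_rows, n_cols : int
        Lattice dimensions; row 0 is the northernmost row.
    x_min, y_min : float
        Lower-left corner of the lower-left cell, decimal degrees.
    cell_size : float
        Square cell edge, decimal degrees.
    nodata_value : float
        Sentinel written to file for missing cells.
    values : ndarray, shape (n_rows, n_cols)
        Cell values; missing cells hold ``nan`` in memory.
    """

    n_rows: int
    n_cols: int
    x_min: float
    y_min: float
    cell_size: float
    nodata_value: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.values.shape != (self.n_rows, self.n_cols):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"(n_rows, n_cols) = ({self.n_rows}, {self.n_cols})"
            )
        with np.errstate(invalid="ignore"):
            self.values[self.values == self.nodata_value] = np.nan
        if np.isinf(self.values).any():
            raise ValueError("grid values must be finite or nodata")

    # -- geometry -----------------------------------------------------------

    @property
    def x_max(self) -> float:
        return self.x_min + self.n_cols * self.cell_size

    @property
    def y_max(self) -> float:
        return self.y_min + self.n_rows * self.cell_size

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where a cell holds data."""
        return ~np.isnan(self.values)

    def copy(self, values: np.ndarray | None = None) -> "Grid":
        """A deep copy, optionally with replaced values on the same geometry."""
        v = self.values.copy() if values is None else np.asarray(values, dtype=float).copy()
        return Grid(self.n_rows, self.n_cols, self.x_min, self.y_min,
                    self.cell_size, self.nodata_value, v)

    def same_geometry(self, other: "Grid") -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and np.isclose(self.x_min, other.x_min)
            and np.isclose(self.y_min, other.y_min)
            and np.isclose(self.cell_size, other.cell_size)
        )

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of the center of cell (row, col)."""
        lon = self.x_min + (col + 0.5) * self.cell_size
        lat = self.y_min + (self.n_rows - row - 0.5) * self.cell_size
        return lon, lat

    def cell_index(self, lon: float, lat: float) -> tuple[int, int] | None:
        """(row, col) containing a point, or None if outside the grid."""
        col = int(np.floor((lon - self.x_min) / self.cell_size))
        row_from_bottom = int(np.floor((lat - self.y_min) / self.cell_size))
        row = self.n_rows - 1 - row_from_bottom
        if 0 <= row < self.n_rows and 0 <= col < self.n_cols:
            return row, col
        return None

    def row_latitudes(self) -> np.ndarray:
        """Cell-center latitude for every row (row 0 = northernmost)."""
        rows = np.arange(self.n_rows)
        return self.y_min + (self.n_rows - rows - 0.5) * self.cell_size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Grid):
            return NotImplemented
        return self.same_geometry(other) and np.array_equal(
            self.values, other.values, equal_nan=True
        )


def cell_area_km2(grid: Grid, row: int) -> float:
    """Area in km^2 of any cell in `row`, on a sphere of radius 6371.0088 km.

    Spherical quadrangle: A = R^2 * dlambda * (sin(phi_top) - sin(phi_bot)).
    Constant along a row; strictly decreasing away from the equator.
    """
    if not 0 <= row < grid.n_rows:
        raise IndexError(f"row {row} out of range [0, {grid.n_rows})")
    lat_top = grid.y_min + (grid.n_rows - row) * grid.cell_size
    lat_bot = lat_top - grid.cell_size
    lat_top = min(lat_top, 90.0)
    lat_bot = max(lat_bot, -90.0)
    dlon = np.radians(grid.cell_size)
    return float(
        EARTH_RADIUS_KM**2 * dlon * (np.sin(np.radians(lat_top)) - np.sin(np.radians(lat_bot)))
    )


def cell_areas_km2(grid: Grid) -> np.ndarray:
    """Per-row cell areas (km^2), shape (n_rows,)."""
    return np.array([cell_area_km2(grid, r) for r in range(grid.n_rows)])


class EnvStack:
    """An ordered, aligned collection of environmental raster layers.

    All layers must share geometry. Nodata masks are harmonized on
    construction: a cell that is nodata in any layer becomes nodata in all
    (mask intersection), so downstream extraction never sees ragged support.
    """

    def __init__(self, layers: Mapping[str, Grid]):
        if not layers:
            raise ValueError("EnvStack requires at least one layer")
        self.layers: dict[str, Grid] = {}
        ref: Grid | None = None
        for name, grid in layers.items():
            if ref is None:
                ref = grid
            elif not grid.same_geometry(ref):
                raise GridAlignmentError(f"layer {name!r} does not align with the first layer")
            self.layers[name] = grid.copy()
        joint = np.ones((ref.n_rows, ref.n_cols), dtype=bool)
        for grid in self.layers.values():
            joint &= grid.mask
        for grid in self.layers.values():
            grid.values[~joint] = np.nan

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def grid(self) -> Grid:
        """The first layer, as the reference geometry."""
        return next(iter(self.layers.values()))

    @property
    def mask(self) -> np.ndarray:
        return self.grid.mask

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, name: str) -> Grid:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def values_at_cells(self, cells: Sequence[tuple[int, int]],
                        names: Sequence[str] | None = None) -> np.ndarray:
        """Matrix of layer values at (row, col) cells, shape (n_cells, n_vars)."""
        names = list(names) if names is not None else self.names
        rows = np.array([c[0] for c in cells], dtype=int)
        cols = np.array([c[1] for c in cells], dtype=int)
        return np.column_stack([self.layers[n].values[rows, cols] for n in names])

    def valid_cells(self) -> list[tuple[int, int]]:
        """All (row, col) with data, row-major order."""
        rr, cc = np.nonzero(self.mask)
        return list(zip(rr.tolist(), cc.tolist()))


@dataclass
class OccurrenceSet:
    """Presence records for one species, decimal degrees WGS84."""

    species: str
    points: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for lon, lat in self.points:
            if not (-180 <= lon <= 180 and -90 <= lat <= 90):
                raise ValueError(f"coordinate out of range: ({lon}, {lat})")

    def __len__(self) -> int:
        return len(self.points)

    def lonlat_array(self) -> np.ndarray:
        return np.array(self.points, dtype=float).reshape(-1, 2)


# -- raster I/O --------------------------------------------------------------


def read_grid(path: str | Path) -> Grid:
    """Read a single-band raster (ESRI ASCII grid or GeoTIFF, by extension)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return _read_geotiff(path)
    return _read_ascii_grid(path)


def write_grid(grid: Grid, path: str | Path) -> None:
    """Write a Grid so that ``read_grid`` recovers it (>= 6 significant digits)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        _write_geotiff(grid, path)
    else:
        _write_ascii_grid(grid, path)


def _read_ascii_grid(path: Path) -> Grid:
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not rows and key in _ASCII_HEADER_KEYS:
                if len(parts) != 2:
                    raise RasterFormatError(f"malformed header line for key {parts[0]!r}")
                try:
                    header[key] = float(parts[1])
                except ValueError as exc:
                    raise RasterFormatError(
                        f"non-numeric value for header key {parts[0]!r}") from exc
            else:
                try:
                    rows.append(np.array(parts, dtype=float))
                except ValueError as exc:
                    raise RasterFormatError(f"non-numeric data row: {line.strip()!r}") from exc
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise RasterFormatError(f"missing required header key {key!r}")
    n_cols = int(header["ncols"])
    n_rows = int(header["nrows"])
    nodata = header.get("nodata_value", -9999.0)
    if len(rows) != n_rows:
        raise RasterFormatError(f"expected {n_rows} data rows, found {len(rows)}")
    for i, r in enumerate(rows):
        if len(r) != n_cols:
            raise RasterFormatError(
                f"row {i} has {len(r)} values but header declares ncols {n_cols}")
    return Grid(n_rows, n_cols, header["xllcorner"], header["yllcorner"],
                header["cellsize"], nodata, np.vstack(rows))


def _write_ascii_grid(grid: Grid, path: Path) -> None:
    vals = grid.values.copy()
    vals[np.isnan(vals)] = grid.nodata_value
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.x_min!r}\n")
        fh.write(f"yllcorner {grid.y_min!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {grid.nodata_value!r}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def _read_geotiff(path: Path) -> Grid:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise RasterFormatError("multi-band / multi-page TIFF input is unsupported")
        page = tif.pages[0]
        data = page.asarray()
        if data.ndim != 2:
            raise RasterFormatError("multi-band TIFF input is unsupported")
        tags = {t.name: t.value for t in page.tags.values()}
    try:
        scale = tags["ModelPixelScaleTag"]
        tiepoint = tags["ModelTiepointTag"]
    except KeyError as exc:
        raise RasterFormatError(f"missing GeoTIFF tag: {exc}") from exc
    cell_x, cell_y = float(scale[0]), float(scale[1])
    if not np.isclose(cell_x, cell_y):
        raise RasterFormatError("non-square cells are unsupported")
    # tiepoint maps raster (0,0) to the upper-left corner coordinate
    x_ul, y_ul = float(tiepoint[3]), float(tiepoint[4])
    nodata = float(tags.get("GDAL_NODATA", -9999.0))
    n_rows, n_cols = data.shape
    return Grid(n_rows, n_cols, x_ul, y_ul - n_rows * cell_y, cell_x, nodata,
                np.asarray(data, dtype=float))


def _write_geotiff(grid: Grid, path: Path) -> None:
    import tifffile

    vals = grid.values.astype(np.float64).copy()
    vals[np.isnan(vals)] = grid.nodata_value
    scale = (grid.cell_size, grid.cell_size, 0.0)
    tiepoint = (0.0, 0.0, 0.0, grid.x_min, grid.y_max, 0.0)
    extratags = [
        (33550, "d", 3, scale, True),           # ModelPixelScaleTag
        (33922, "d", 6, tiepoint, True),        # ModelTiepointTag
        (42113, "s", 0, f"{grid.nodata_value!r}", True),  # GDAL_NODATA
    ]
    tifffile.imwrite(path, vals, extratags=extratags)


# -- occurrences -------------------------------------------------------------


def load_occurrences(path: str | Path) -> OccurrenceSet:
    """Load an occurrence CSV with header ``species,longitude,latitude``.

    Rows with out-of-range or non-numeric coordinates are rejected and
    reported (by 1-based data row number) in a warning; valid rows survive.
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = {"species", "longitude", "latitude"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"occurrence CSV missing column(s): {sorted(missing)}")
    if df.empty:
        warnings.warn(f"occurrence file {path} contains no data rows")
        return OccurrenceSet(species="", points=[])
    species = str(df["species"].iloc[0])
    points: list[tuple[float, float]] = []
    bad_rows: list[int] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            lon = float(row.longitude)
            lat = float(row.latitude)
        except (TypeError, ValueError):
            bad_rows.append(i)
            continue
        if not (np.isfinite(lon) and np.isfinite(lat)
                and -180 <= lon <= 180 and -90 <= lat <= 90):
            bad_rows.append(i)
            continue
        points.append((lon, lat))
    if bad_rows:
        warnings.warn(f"rejected {len(bad_rows)} occurrence row(s) with invalid "
                      f"coordinates: rows {bad_rows}")
    return OccurrenceSet(species=species, points=points)


def save_occurrences(occ: OccurrenceSet, path: str | Path) -> None:
    import pandas as pd

    arr = occ.lonlat_array()
    pd.DataFrame({
        "species": [occ.species] * len(occ),
        "longitude": arr[:, 0] if len(occ) else [],
        "latitude": arr[:, 1] if len(occ) else [],
    }).to_csv(path, index=False)


def clean_occurrences(occ: OccurrenceSet, grid: Grid) -> OccurrenceSet:
    """Deduplicate and thin occurrences to at most one point per grid cell.

    Keeps the first point (input order) in each occupied cell; drops points
    outside the grid or on nodata cells. Idempotent.
    """
    seen_cells: set[tuple[int, int]] = set()
    kept: list[tuple[float, float]] = []
    for lon, lat in occ.points:
        idx = grid.cell_index(lon, lat)
        if idx is None:
            continue
        if np.isnan(grid.values[idx]):
            continue
        if idx in seen_cells:
            continue
        seen_cells.add(idx)
        kept.append((lon, lat))
    return OccurrenceSet(species=occ.species, points=kept)


def occurrence_cells(occ: OccurrenceSet, grid: Grid) -> list[tuple[int, int]]:
    """Distinct (row, col) cells of the occurrences, in input order."""
    cells: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    for lon, lat in occ.points:
        idx = grid.cell_index(lon, lat)
        if idx is not None and not np.isnan(grid.values[idx]) and idx not in seen:
            seen.add(idx)
            cells.append(idx)
    return cells
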