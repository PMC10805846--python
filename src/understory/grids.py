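"""Regular lat/lon grids, rasters and geodesic helpers.

All coordinates are geographic (WGS84 lat/lon, decimal degrees).  A
:class:`Grid` is a regular cell-centre-registered lattice described by its
lower-left corner, cell size in degrees, and shape; a :class:`Raster` couples
a grid with a 2-D value array whose row 0 is the *northernmost* row (the usual
raster convention).  Distances between points are great-circle (haversine) in
kilometres — the analyses here span whole continents, so no single projected
CRS would do.

Raster files are single-band ESRI ASCII grids (``.asc``), a plain-text
georeferenced format readable by any GIS.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

EARTH_RADIUS_KM = 6371.0088
#: kilometres per degree of latitude (and of longitude at the equator)
KM_PER_DEG = EARTH_RADIUS_KM * np.pi / 180.0

DEFAULT_NODATA = -9999.0


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or broadcastable arrays.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def initial_bearing_deg(lat1, lon1, lat2, lon2):
    """Initial great-circle bearing from point 1 to point 2, degrees in [0, 360)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.degrees(np.arctan2(y, x)) % 360.0


@dataclass(frozen=True)
class Grid:
    """Regular geographic grid.

    Parameters
    ----------
    nrows, ncols
        Shape of the lattice.
    lat_min, lon_min
        Latitude/longitude of the *lower-left corner* of the lower-left cell
        (i.e. the grid's bounding-box corner, not a cell centre).
    cell_size
        Cell edge length in degrees (square cells).
    """

    nrows: int
    ncols: int
    lat_min: float
    lon_min: float
    cell_size: float

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def lat_max(self) -> float:
        return self.lat_min + self.nrows * self.cell_size

    @property
    def lon_max(self) -> float:
        return self.lon_min + self.ncols * self.cell_size

    def cell_center_lats(self) -> np.ndarray:
        """Cell-centre latitudes per raster row (row 0 is northernmost)."""
        return self.lat_max - (np.arange(self.nrows) + 0.5) * self.cell_size

    def cell_center_lons(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.ncols) + 0.5) * self.cell_size

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(lat, lon) 2-D arrays of all cell centres."""
        lats = self.cell_center_lats()
        lons = self.cell_center_lons()
        return np.broadcast_to(lats[:, None], self.shape).copy(), np.broadcast_to(lons[None, :], self.shape).copy()

    def contains(self, lat: float, lon: float) -> bool:
        return (self.lat_min <= lat <= self.lat_max) and (self.lon_min <= lon <= self.lon_max)

    def index_of(self, lat: float, lon: float) -> tuple[int, int]:
        """(row, col) of the cell containing the point; raises KeyError off-grid."""
        if not self.contains(lat, lon):
            raise KeyError(f"point (lat={lat}, lon={lon}) is outside grid extent "
                           f"[{self.lat_min}, {self.lat_max}] x [{self.lon_min}, {self.lon_max}]")
        row = int(np.clip((self.lat_max - lat) / self.cell_size, 0, self.nrows - 1))
        col = int(np.clip((lon - self.lon_min) / self.cell_size, 0, self.ncols - 1))
        return row, col


@dataclass
class Raster:
    """A single-band value array on a :class:`Grid` with an explicit no-data value."""

    grid: Grid
    values: np.ndarray
    nodata: float = DEFAULT_NODATA

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(f"values shape {self.values.shape} != grid shape {self.grid.shape}")

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where data is valid."""
        return ~np.isclose(self.values, self.nodata) & ~np.isnan(self.values)

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def copy_with(self, values: np.ndarray) -> "Raster":
        return Raster(self.grid, np.asarray(values, dtype=float), self.nodata)


def same_grid(a: Grid, b: Grid, tol: float = 1e-9) -> bool:
    return (a.nrows == b.nrows and a.ncols == b.ncols
            and abs(a.lat_min - b.lat_min) <= tol
            and abs(a.lon_min - b.lon_min) <= tol
            and abs(a.cell_size - b.cell_size) <= tol)


class AlignmentError(ValueError):
    """Two rasters expected on the same grid are not."""


def require_same_grid(a: Raster, b: Raster) -> None:
    if not same_grid(a.grid, b.grid):
        raise AlignmentError(f"grid mismatch: {a.grid} vs {b.grid}")


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def write_ascii_grid(raster: Raster, path: str | Path) -> Path:
    """Write a raster as an ESRI ASCII grid (cell-corner registered header)."""
    path = Path(path)
    g = raster.grid
    vals = np.where(raster.mask, raster.values, raster.nodata)
    header = (f"ncols {g.ncols}\n"
              f"nrows {g.nrows}\n"
              f"xllcorner {g.lon_min!r}\n"
              f"yllcorner {g.lat_min!r}\n"
              f"cellsize {g.cell_size!r}\n"
              f"NODATA_value {raster.nodata!r}\n")
    with open(path, "w") as fh:
        fh.write(header)
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")
    return path


def read_ascii_grid(path: str | Path) -> Raster:
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"} and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append(np.array(parts, dtype=float))
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"{path}: missing ASCII grid header field '{req}'")
    grid = Grid(nrows=int(header["nrows"]), ncols=int(header["ncols"]),
                lat_min=header["yllcorner"], lon_min=header["xllcorner"],
                cell_size=header["cellsize"])
    values = np.vstack(rows)
    if values.shape != grid.shape:
        raise ValueError(f"{path}: data shape {values.shape} does not match header {grid.shape}")
    return Raster(grid, values, nodata=header.get("nodata_value", DEFAULT_NODATA))


def write_raster_bundle(rasters: dict[str, Raster], directory: str | Path) -> Path:
    """Write several named rasters as .asc files plus an index.json manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index = {}
    for name, ras in rasters.items():
        p = write_ascii_grid(ras, directory / f"{name}.asc")
        index[name] = p.name
    with open(directory / "index.json", "w") as fh:
        json.dump(index, fh, indent=1, sort_keys=True)
    return directory
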