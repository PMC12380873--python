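"""Gridded raster and region-polygon primitives shared across the pipeline.

Rasters follow the ESRI ASCII grid convention: square cells in degrees,
lower-left corner registration, row 0 of the value array is the
northernmost row.  All values are held as float64 with NaN marking nodata;
the NODATA_value sentinel only exists on disk.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from shapely import contains_xy
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

EARTH_RADIUS_KM = 6371.0088

__all__ = [
    "EARTH_RADIUS_KM",
    "Grid",
    "Raster",
    "Stack",
    "RegionSet",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_stack",
    "write_stack",
    "haversine_km",
    "initial_bearing_deg",
    "bearing_quadrant",
]


@dataclass(frozen=True)
class Grid:
    """Georeference of a regular lon/lat grid (degrees)."""

    ncols: int
    nrows: int
    xllcorner: float
    yllcorner: float
    cellsize: float

    def __post_init__(self) -> None:
        if self.ncols < 1 or self.nrows < 1:
            raise ValueError("grid needs at least one row and one column")
        if not self.cellsize > 0:
            raise ValueError("cellsize must be positive")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) in degrees."""
        return (
            self.xllcorner,
            self.xllcorner + self.ncols * self.cellsize,
            self.yllcorner,
            self.yllcorner + self.nrows * self.cellsize,
        )

    def lon_centers(self) -> np.ndarray:
        return self.xllcorner + (np.arange(self.ncols) + 0.5) * self.cellsize

    def lat_centers(self) -> np.ndarray:
        """Latitude of each row center, row 0 = northernmost."""
        top = self.yllcorner + self.nrows * self.cellsize
        return top - (np.arange(self.nrows) + 0.5) * self.cellsize

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) 2-D arrays of cell centers, shaped (nrows, ncols)."""
        return np.meshgrid(self.lon_centers(), self.lat_centers())

    def index_of(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cells containing the given points.

        Points outside the extent get out-of-range indices; callers mask
        with :meth:`in_bounds`.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.xllcorner) / self.cellsize).astype(int)
        top = self.yllcorner + self.nrows * self.cellsize
        row = np.floor((top - lat) / self.cellsize).astype(int)
        return row, col

    def in_bounds(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        xmin, xmax, ymin, ymax = self.extent
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (lon >= xmin) & (lon < xmax) & (lat >= ymin) & (lat < ymax)


@dataclass
class Raster:
    """A single gridded layer; NaN marks nodata."""

    values: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.nrows, self.grid.ncols):
            raise ValueError(
                f"value array shape {self.values.shape} does not match grid "
                f"({self.grid.nrows}, {self.grid.ncols})"
            )

    @property
    def mask(self) -> np.ndarray:
        """True where the cell carries data."""
        return np.isfinite(self.values)

    def sample(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        """Cell values at the given points; NaN outside the extent."""
        row, col = self.grid.index_of(lon, lat)
        ok = self.grid.in_bounds(lon, lat)
        out = np.full(np.shape(ok), np.nan)
        out[ok] = self.values[row[ok], col[ok]]
        return out


@dataclass
class Stack:
    """Named co-registered environmental layers."""

    grid: Grid
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (self.grid.nrows, self.grid.ncols):
                raise ValueError(f"layer {name!r} does not share the stack grid")
            self.layers[name] = arr

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, name: str) -> Raster:
        return Raster(self.layers[name], self.grid)

    def valid_mask(self) -> np.ndarray:
        """Cells where every layer is finite."""
        m = np.ones((self.grid.nrows, self.grid.ncols), dtype=bool)
        for arr in self.layers.values():
            m &= np.isfinite(arr)
        return m

    def matrix(self, mask: np.ndarray | None = None) -> np.ndarray:
        """(n_cells, n_layers) matrix over `mask` (default: all-valid cells)."""
        if mask is None:
            mask = self.valid_mask()
        return np.column_stack([arr[mask] for arr in self.layers.values()])

    def subset(self, names: list[str]) -> "Stack":
        return Stack(self.grid, {n: self.layers[n] for n in names})

    def sample(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        """(n_points, n_layers) matrix of layer values at points."""
        return np.column_stack(
            [Raster(arr, self.grid).sample(lon, lat) for arr in self.layers.values()]
        )


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid; NODATA cells become NaN.

    Raises ValueError with the offending line number on malformed headers.
    """
    path = Path(path)
    header: dict[str, float] = {}
    nodata = -9999.0
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
            key = parts[0].lower()
            try:
                val = float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}: line {i + 1}: bad header value {parts[1]!r}") from exc
            if key == "nodata_value":
                nodata = val
            else:
                header[key] = val
            n_header = i + 1
        else:
            break
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise ValueError(f"{path}: line {n_header + 1}: missing header keys {missing}")
    grid = Grid(
        ncols=int(header["ncols"]),
        nrows=int(header["nrows"]),
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        cellsize=header["cellsize"],
    )
    try:
        values = np.loadtxt(lines[n_header:], ndmin=2)
    except ValueError as exc:
        raise ValueError(f"{path}: malformed data section: {exc}") from exc
    if values.shape != (grid.nrows, grid.ncols):
        raise ValueError(
            f"{path}: data shape {values.shape} does not match header "
            f"({grid.nrows}, {grid.ncols})"
        )
    values[values == nodata] = np.nan
    return Raster(values, grid)


def write_ascii_grid(raster: Raster, path: str | Path, nodata: float = -9999.0) -> Path:
    """Write an ESRI ASCII grid; %.17g preserves float64 round trips."""
    path = Path(path)
    g = raster.grid
    vals = raster.values.copy()
    vals[~np.isfinite(vals)] = nodata
    with open(path, "w") as fh:
        fh.write(f"ncols {g.ncols}\n")
        fh.write(f"nrows {g.nrows}\n")
        fh.write(f"xllcorner {g.xllcorner!r}\n")
        fh.write(f"yllcorner {g.yllcorner!r}\n")
        fh.write(f"cellsize {g.cellsize!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")
    return path


def write_stack(stack: Stack, directory: str | Path) -> Path:
    """Write one .asc per layer plus a YAML manifest; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for name, arr in stack.layers.items():
        fname = f"{name}.asc"
        write_ascii_grid(Raster(arr, stack.grid), directory / fname)
        entries.append({"name": name, "file": fname})
    manifest = directory / "manifest.yaml"
    with open(manifest, "w") as fh:
        yaml.safe_dump({"layers": entries}, fh, sort_keys=False)
    return manifest


def read_stack(source: str | Path) -> Stack:
    """Read a stack from a manifest path or a directory holding one."""
    source = Path(source)
    manifest = source / "manifest.yaml" if source.is_dir() else source
    with open(manifest) as fh:
        meta = yaml.safe_load(fh)
    layers: dict[str, np.ndarray] = {}
    grid: Grid | None = None
    for entry in meta["layers"]:
        rast = read_ascii_grid(manifest.parent / entry["file"])
        if grid is None:
            grid = rast.grid
        elif rast.grid != grid:
            raise ValueError(f"layer {entry['name']!r} does not share the stack grid")
        layers[entry["name"]] = rast.values
    assert grid is not None
    return Stack(grid, layers)


# ---------------------------------------------------------------------------
# Region polygons
# ---------------------------------------------------------------------------


@dataclass
class RegionSet:
    """Named polygons used for zonal summaries."""

    ids: list[str]
    geometries: list[BaseGeometry]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.geometries):
            raise ValueError("ids and geometries must align")

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(zip(self.ids, self.geometries))

    def assign_cells(self, grid: Grid) -> np.ndarray:
        """Region index (into self.ids) of each cell center, -1 if none.

        Overlapping regions resolve first-match with a warning.
        """
        lon, lat = grid.center_mesh()
        assign = np.full(lon.shape, -1, dtype=int)
        overlapped = False
        for idx, geom in enumerate(self.geometries):
            inside = contains_xy(geom, lon, lat)
            if np.any(inside & (assign != -1)):
                overlapped = True
            assign[inside & (assign == -1)] = idx
        if overlapped:
            warnings.warn("overlapping regions: cells assigned to first match")
        return assign

    def to_geojson(self, path: str | Path) -> Path:
        features = [
            {
                "type": "Feature",
                "properties": {"id": rid},
                "geometry": mapping(geom),
            }
            for rid, geom in self
        ]
        path = Path(path)
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)
        return path

    @classmethod
    def from_geojson(cls, path: str | Path) -> "RegionSet":
        with open(path) as fh:
            fc = json.load(fh)
        ids, geoms = [], []
        for feat in fc["features"]:
            ids.append(str(feat["properties"]["id"]))
            geoms.append(shape(feat["geometry"]))
        return cls(ids, geoms)


# ---------------------------------------------------------------------------
# Great-circle helpers
# ---------------------------------------------------------------------------


def haversine_km(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Great-circle distance in km on a sphere of radius EARTH_RADIUS_KM."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def initial_bearing_deg(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Initial great-circle bearing from point 1 to point 2, degrees in [0, 360)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dlam = math.radians(lon2 - lon1)
    x = math.sin(dlam) * math.cos(p2)
    y = math.cos(p1) * math.sin(p2) - math.sin(p1) * math.cos(p2) * math.cos(dlam)
    return math.degrees(math.atan2(x, y)) % 360.0


_QUADRANTS = (
    "northward",
    "northeastward",
    "eastward",
    "southeastward",
    "southward",
    "southwestward",
    "westward",
    "northwestward",
)


def bearing_quadrant(bearing_deg: float) -> str:
    """Eight-wind verbal direction for a bearing in degrees."""
    sector = int(((bearing_deg % 360.0) + 22.5) // 45.0) % 8
    return _QUADRANTS[sector]
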