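"""Suitability geography.

Fisher-Jenks natural-breaks classification, spherical cell areas, zonal
area accounting over region polygons, class centroids, great-circle
centroid migration, and period-to-period change summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import (
    EARTH_RADIUS_KM,
    Grid,
    Raster,
    RegionSet,
    bearing_quadrant,
    haversine_km,
    initial_bearing_deg,
)

__all__ = [
    "CLASS_NAMES",
    "CentroidShift",
    "jenks_breaks",
    "classify",
    "cell_area_km2",
    "regional_summary",
    "class_centroid",
    "centroid_shift",
    "change_summary",
]

# class index -> label for the default 3-level scheme
CLASS_NAMES = {0: "unsuitable", 1: "low", 2: "high"}


def jenks_breaks(values, k: int = 3) -> np.ndarray:
    """Fisher-Jenks optimal 1-D classification into k classes.

    Dynamic program minimizing the within-class sum of squared deviations;
    returns the k-1 upper break values (the maximum of each class but the
    last).  Requires at least k distinct values.
    """
    v = np.sort(np.asarray(values, dtype=float).ravel())
    v = v[np.isfinite(v)]
    n = v.size
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return np.array([])
    if np.unique(v).size < k:
        raise ValueError(f"need at least {k} distinct values")

    # prefix sums for O(1) segment cost: SSD of v[i:j]
    s1 = np.concatenate([[0.0], np.cumsum(v)])
    s2 = np.concatenate([[0.0], np.cumsum(v * v)])

    def seg_cost_vec(i_arr: np.ndarray, j: int) -> np.ndarray:
        length = j - i_arr
        su = s1[j] - s1[i_arr]
        return (s2[j] - s2[i_arr]) - su * su / length

    INF = np.inf
    # cost[c, j]: optimal SSD of v[:j] split into c+1 classes
    cost = np.full((k, n + 1), INF)
    back = np.zeros((k, n + 1), dtype=int)
    idx = np.arange(n + 1)
    for j in range(1, n + 1):
        cost[0, j] = seg_cost_vec(np.array([0]), j)[0]
    for c in range(1, k):
        for j in range(c + 1, n + 1):
            i_arr = idx[c:j]  # split points: previous classes end at i
            cand = cost[c - 1, i_arr] + seg_cost_vec(i_arr, j)
            best = int(np.argmin(cand))
            cost[c, j] = cand[best]
            back[c, j] = i_arr[best]

    # recover class boundaries
    bounds = []
    j = n
    for c in range(k - 1, 0, -1):
        i = back[c, j]
        bounds.append(i)
        j = i
    bounds = bounds[::-1]  # start indices of classes 2..k
    return np.array([v[b - 1] for b in bounds])


def classify(raster: Raster, breaks) -> Raster:
    """Classify a raster into len(breaks)+1 classes by half-open intervals.

    Class c covers (b_{c-1}, b_c] with b_0 = -inf; values exactly at a break
    fall in the lower class.  Nodata propagates as NaN.
    """
    breaks = np.asarray(breaks, dtype=float)
    if breaks.size and np.any(np.diff(breaks) <= 0):
        raise ValueError("breaks must be strictly increasing")
    vals = raster.values
    cls = np.digitize(vals, breaks, right=True).astype(float)
    cls[~np.isfinite(vals)] = np.nan
    return Raster(cls, raster.grid)


def cell_area_km2(grid: Grid) -> np.ndarray:
    """Area (km^2) of one cell in each latitude row, row 0 = northernmost.

    A = R^2 * dlon_rad * |sin(lat_top) - sin(lat_bottom)|.
    """
    top = grid.yllcorner + grid.nrows * grid.cellsize
    edges = top - np.arange(grid.nrows + 1) * grid.cellsize
    if np.any(np.abs(edges) > 90 + 1e-9):
        raise ValueError("grid latitudes exceed +/-90 degrees")
    edges = np.clip(edges, -90.0, 90.0)
    sin_edges = np.sin(np.radians(edges))
    dlon = np.radians(grid.cellsize)
    return EARTH_RADIUS_KM**2 * dlon * np.abs(sin_edges[:-1] - sin_edges[1:])


def _area_grid(grid: Grid) -> np.ndarray:
    return np.repeat(cell_area_km2(grid)[:, None], grid.ncols, axis=1)


def regional_summary(classmap: Raster, regions: RegionSet) -> pd.DataFrame:
    """Area (km^2) per region and class; cells assigned by center containment.

    Returns a long DataFrame with columns region_id, class, area_km2;
    regions without cells appear with zero rows for the observed classes.
    """
    assign = regions.assign_cells(classmap.grid)
    areas = _area_grid(classmap.grid)
    vals = classmap.values
    finite = np.isfinite(vals)
    classes = sorted(int(c) for c in np.unique(vals[finite]))
    rows = []
    for ridx, rid in enumerate(regions.ids):
        in_region = (assign == ridx) & finite
        for c in classes:
            sel = in_region & (vals == c)
            rows.append({"region_id": rid, "class": c,
                         "area_km2": float(areas[sel].sum())})
    return pd.DataFrame(rows)


def class_totals(classmap: Raster) -> pd.Series:
    """Total classified area (km^2) per class over the whole raster."""
    areas = _area_grid(classmap.grid)
    vals = classmap.values
    finite = np.isfinite(vals)
    out = {}
    for c in sorted(int(c) for c in np.unique(vals[finite])):
        out[c] = float(areas[finite & (vals == c)].sum())
    return pd.Series(out, name="area_km2")


def class_centroid(classmap: Raster, classes) -> tuple[float, float]:
    """Area-weighted (lon, lat) centroid of cells in the selected class(es)."""
    if np.isscalar(classes):
        classes = [classes]
    vals = classmap.values
    sel = np.isfinite(vals) & np.isin(vals, list(classes))
    if not sel.any():
        raise ValueError("selected class is empty")
    lon, lat = classmap.grid.center_mesh()
    w = _area_grid(classmap.grid)[sel]
    return (
        float(np.average(lon[sel], weights=w)),
        float(np.average(lat[sel], weights=w)),
    )


@dataclass(frozen=True)
class CentroidShift:
    lon1: float
    lat1: float
    lon2: float
    lat2: float
    distance_km: float
    bearing_deg: float
    direction: str

    def as_dict(self) -> dict:
        return {
            "from": {"lon": self.lon1, "lat": self.lat1},
            "to": {"lon": self.lon2, "lat": self.lat2},
            "distance_km": self.distance_km,
            "bearing_deg": self.bearing_deg,
            "direction": self.direction,
        }


def centroid_shift(c1: tuple[float, float], c2: tuple[float, float]) -> CentroidShift:
    """Great-circle migration between two (lon, lat) centroids."""
    lon1, lat1 = c1
    lon2, lat2 = c2
    for lat in (lat1, lat2):
        if abs(lat) > 90:
            raise ValueError("latitude out of range")
    dist = haversine_km(lon1, lat1, lon2, lat2)
    bearing = initial_bearing_deg(lon1, lat1, lon2, lat2)
    return CentroidShift(lon1, lat1, lon2, lat2, dist, bearing,
                         bearing_quadrant(bearing))


def change_summary(summary_t1: pd.DataFrame, summary_t2: pd.DataFrame) -> pd.DataFrame:
    """Per-class area change between two regional summaries.

    change_pct = 100 * (A2 - A1) / A1; NaN where the first-period area is
    zero (undefined relative change).
    """
    a1 = summary_t1.groupby("class")["area_km2"].sum()
    a2 = summary_t2.groupby("class")["area_km2"].sum()
    classes = sorted(set(a1.index) | set(a2.index))
    rows = []
    for c in classes:
        v1 = float(a1.get(c, 0.0))
        v2 = float(a2.get(c, 0.0))
        if v1 == 0:
            pct = np.nan
            if v2 != 0:
                warnings.warn(f"class {c}: first-period area is zero, change% undefined")
        else:
            pct = 100.0 * (v2 - v1) / v1
        rows.append({"class": c, "area_t1_km2": v1, "area_t2_km2": v2,
                     "change_km2": v2 - v1, "change_pct": pct})
    return pd.DataFrame(rows)
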