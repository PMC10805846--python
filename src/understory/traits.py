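"""Thermal traits: temperature offset, diurnal range, and zonal stratification.

The temperature offset ΔT = T_under − T_open compares the modelled understory
surface against the open-air macroclimate on the same grid; negative values
mean a cooler understory.  The diurnal range R_T = T_dt − T_nt measures the
day-night contrast.  For stratified reporting the tropics are partitioned
into 18 zones: three elevation bands — low [0, 500), mid [500, 1000), high
[1000, ∞) m a.s.l. — crossed with six latitude bands — low [0°, 5°), mid
[5°, 10°), high [10°, 23.45°] in each hemisphere (lat = 0 counts as North).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .grids import Raster, require_same_grid
from .synthetic import TROPIC_LAT

ELEVATION_CLASSES = ("low", "mid", "high")
ELEVATION_EDGES = (0.0, 500.0, 1000.0)       # lower-inclusive band starts
LATITUDE_CLASSES = ("low", "mid", "high")
LATITUDE_EDGES = (0.0, 5.0, 10.0)

#: the 18 possible zone labels, e.g. "low:low-N"
ALL_ZONES = tuple(f"{e}:{l}-{h}" for e, l, h in
                  itertools.product(ELEVATION_CLASSES, LATITUDE_CLASSES, ("N", "S")))


def temperature_offset(t_under: Raster, t_open: Raster) -> Raster:
    """ΔT = T_under − T_open, elementwise; no-data propagates."""
    require_same_grid(t_under, t_open)
    ok = t_under.mask & t_open.mask
    values = np.where(ok, t_under.values - t_open.values, t_under.nodata)
    return Raster(t_under.grid, values, t_under.nodata)


def diurnal_range(t_dt: Raster, t_nt: Raster) -> Raster:
    """R_T = T_dt − T_nt, elementwise; computed only where both are valid."""
    require_same_grid(t_dt, t_nt)
    ok = t_dt.mask & t_nt.mask
    values = np.where(ok, t_dt.values - t_nt.values, t_dt.nodata)
    return Raster(t_dt.grid, values, t_dt.nodata)


def _band(value: float, edges: tuple[float, ...], classes: tuple[str, ...]) -> str:
    idx = 0
    for i, lo in enumerate(edges):
        if value >= lo:
            idx = i
    return classes[idx]


def classify_zone(lat: float, elevation: float) -> str:
    """Zone label 'elev:lat-hemisphere' for a point; bands lower-inclusive.

    lat = 0 is assigned to the Northern classes; |lat| beyond the tropic is a
    domain error, negative elevation a value error.
    """
    if abs(lat) > TROPIC_LAT + 1e-9:
        raise ValueError(f"latitude {lat} outside the tropics (|lat| <= {TROPIC_LAT})")
    if elevation < 0:
        raise ValueError(f"negative elevation {elevation}")
    elev_cls = _band(elevation, ELEVATION_EDGES, ELEVATION_CLASSES)
    lat_cls = _band(abs(lat), LATITUDE_EDGES, LATITUDE_CLASSES)
    hemi = "N" if lat >= 0 else "S"
    return f"{elev_cls}:{lat_cls}-{hemi}"


def zone_raster(elevation: Raster, mask: np.ndarray | None = None) -> np.ndarray:
    """Per-cell zone labels (object array) for all (optionally masked) cells."""
    grid = elevation.grid
    lat2d, _ = grid.center_mesh()
    elev = np.clip(elevation.values, 0.0, None)
    elev_idx = np.searchsorted(ELEVATION_EDGES[1:], elev, side="right")
    lat_idx = np.searchsorted(LATITUDE_EDGES[1:], np.abs(lat2d), side="right")
    hemi = np.where(lat2d >= 0, "N", "S")
    labels = np.empty(grid.shape, dtype=object)
    for (r, c), _ in np.ndenumerate(labels):
        labels[r, c] = f"{ELEVATION_CLASSES[elev_idx[r, c]]}:{LATITUDE_CLASSES[lat_idx[r, c]]}-{hemi[r, c]}"
    if mask is not None:
        labels[~mask] = None
    return labels


def zonal_summary(trait_maps: dict[str, Raster], zones: np.ndarray,
                  month: int | None = None) -> pd.DataFrame:
    """Per-zone count / mean / sd for each trait raster.

    All 18 zones appear in the output; zones with no valid cells report
    count 0 and NaN statistics.
    """
    rows = []
    for trait, raster in trait_maps.items():
        valid = raster.mask & (zones != None)  # noqa: E711  — object-array comparison
        vals = raster.values
        for zone in ALL_ZONES:
            sel = valid & (zones == zone)
            n = int(sel.sum())
            rows.append({
                "zone": zone, "month": month, "trait": trait, "n": n,
                "mean": float(vals[sel].mean()) if n else np.nan,
                "sd": float(vals[sel].std(ddof=0)) if n else np.nan,
            })
    return pd.DataFrame(rows, columns=["zone", "month", "trait", "n", "mean", "sd"])
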