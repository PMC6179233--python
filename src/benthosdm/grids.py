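"""Gridded surfaces, management-zone polygons, and plain-text spatial IO.

The package works on single-band 2-D rasters (`GridSurface`) with a square
cell size and NaN as the in-memory nodata marker.  Grid indexing is
row-major and 0-based with cell (0, 0) at the north-west corner; cells are
half-open intervals ``[x, x + cell_size)`` in both axes, so a point on a
boundary belongs to exactly one cell.

Rasters are persisted as ESRI ASCII grids (a plain-text, GDAL-readable
format); zone polygons as GeoJSON FeatureCollections; site tables as CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, mapping, shape

NODATA = -9999.0

__all__ = [
    "GridSurface",
    "Zone",
    "ZoneSet",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_zones_geojson",
    "write_zones_geojson",
    "read_sites_csv",
    "write_sites_csv",
    "SITE_BASE_COLUMNS",
]

#: mandatory leading columns of every site table
SITE_BASE_COLUMNS = ["site_id", "x", "y", "presence"]


@dataclass
class GridSurface:
    """A single-band raster: float values, square cells, NaN = nodata.

    ``x_origin``/``y_origin`` locate the lower-left (south-west) corner of
    the grid in map coordinates; row 0 is the northernmost row.
    """

    values: np.ndarray
    cell_size: float = 2.0
    x_origin: float = 0.0
    y_origin: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("GridSurface requires a 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def cell_area(self) -> float:
        return self.cell_size * self.cell_size

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds valid data."""
        return ~np.isnan(self.values)

    def x_centers(self) -> np.ndarray:
        """Map x-coordinate of each column's cell centre."""
        return self.x_origin + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        """Map y-coordinate of each row's cell centre (row 0 = north)."""
        return self.y_origin + (self.n_rows - np.arange(self.n_rows) - 0.5) * self.cell_size

    def center_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) centre coordinates as full 2-D arrays."""
        xs, ys = np.meshgrid(self.x_centers(), self.y_centers())
        return xs, ys

    def cell_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing each point (half-open rule).

        Points outside the grid bounds raise ``ValueError``.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x_origin) / self.cell_size).astype(int)
        # y increases northwards; row 0 is the top (north) row
        row = self.n_rows - 1 - np.floor((y - self.y_origin) / self.cell_size).astype(int)
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        if np.any(bad):
            raise ValueError(f"{int(np.sum(bad))} point(s) fall outside the grid bounds")
        return row, col

    def value_at(self, x, y) -> np.ndarray:
        row, col = self.cell_of(x, y)
        return self.values[row, col]

    # -- algebra ----------------------------------------------------------
    def aligned_with(self, other: "GridSurface") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.isclose(self.x_origin, other.x_origin)
            and np.isclose(self.y_origin, other.y_origin)
        )

    def like(self, values: np.ndarray) -> "GridSurface":
        """A new surface with the same geometry and the given values."""
        return GridSurface(np.asarray(values, dtype=float), self.cell_size, self.x_origin, self.y_origin)

    def copy(self) -> "GridSurface":
        return self.like(self.values.copy())


def require_aligned(*grids: GridSurface) -> None:
    first = grids[0]
    for g in grids[1:]:
        if not first.aligned_with(g):
            raise ValueError("grids are not aligned (shape, cell size or origin differ)")


# ---------------------------------------------------------------------------
# Zones
# ---------------------------------------------------------------------------

ZONE_TYPES = ("exclusion", "operation", "corridor", "feature")


@dataclass
class Zone:
    """One management polygon with an identifier and a type tag."""

    zone_id: str
    zone_type: str
    polygon: Polygon

    def __post_init__(self) -> None:
        if self.zone_type not in ZONE_TYPES:
            raise ValueError(f"unknown zone_type {self.zone_type!r}; expected one of {ZONE_TYPES}")
        if not self.polygon.is_valid or self.polygon.is_empty:
            raise ValueError(f"zone {self.zone_id!r}: polygon is invalid or empty")


@dataclass
class ZoneSet:
    """A collection of simple, uniquely identified zone polygons."""

    zones: list[Zone] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [z.zone_id for z in self.zones]
        if len(ids) != len(set(ids)):
            raise ValueError("zone ids are not unique")

    def __len__(self) -> int:
        return len(self.zones)

    def __iter__(self):
        return iter(self.zones)

    def of_type(self, zone_type: str) -> "ZoneSet":
        return ZoneSet([z for z in self.zones if z.zone_type == zone_type])

    def check_non_overlapping(self, tol: float = 1e-9) -> None:
        """Raise if any two zone interiors overlap (area accounting is ambiguous)."""
        zs = self.zones
        for i in range(len(zs)):
            for j in range(i + 1, len(zs)):
                inter = zs[i].polygon.intersection(zs[j].polygon)
                if inter.area > tol:
                    raise ValueError(
                        f"zones {zs[i].zone_id!r} and {zs[j].zone_id!r} overlap "
                        f"(shared area {inter.area:.3g})"
                    )

    def contains_centers(self, grid: GridSurface) -> dict[str, np.ndarray]:
        """Per-zone boolean membership mask of grid-cell centres."""
        xs, ys = grid.center_grids()
        out = {}
        for z in self.zones:
            inside = shapely.contains_xy(z.polygon, xs.ravel(), ys.ravel())
            out[z.zone_id] = inside.reshape(grid.shape)
        return out


# ---------------------------------------------------------------------------
# Plain-text IO
# ---------------------------------------------------------------------------

def write_ascii_grid(grid: GridSurface, path) -> None:
    """Write a GridSurface as an ESRI ASCII grid (nodata = -9999)."""
    vals = np.where(np.isnan(grid.values), NODATA, grid.values)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.x_origin}\n"
        f"yllcorner {grid.y_origin}\n"
        f"cellsize {grid.cell_size}\n"
        f"NODATA_value {NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.8g")


def read_ascii_grid(path) -> GridSurface:
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    vals = np.atleast_2d(vals)
    nodata = hdr.get("nodata_value", NODATA)
    vals[vals == nodata] = np.nan
    return GridSurface(
        vals,
        cell_size=hdr["cellsize"],
        x_origin=hdr["xllcorner"],
        y_origin=hdr["yllcorner"],
    )


def write_zones_geojson(zones: ZoneSet, path) -> None:
    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"zone_id": z.zone_id, "zone_type": z.zone_type},
                "geometry": mapping(z.polygon),
            }
            for z in zones
        ],
    }
    with open(path, "w") as fh:
        json.dump(fc, fh, indent=1)


def read_zones_geojson(path) -> ZoneSet:
    with open(path) as fh:
        fc = json.load(fh)
    zones = [
        Zone(
            zone_id=str(feat["properties"]["zone_id"]),
            zone_type=feat["properties"]["zone_type"],
            polygon=shape(feat["geometry"]),
        )
        for feat in fc["features"]
    ]
    return ZoneSet(zones)


def write_sites_csv(sites: pd.DataFrame, path) -> None:
    missing = [c for c in SITE_BASE_COLUMNS if c not in sites.columns]
    if missing:
        raise ValueError(f"site table missing required columns: {missing}")
    ordered = SITE_BASE_COLUMNS + [c for c in sites.columns if c not in SITE_BASE_COLUMNS]
    sites[ordered].to_csv(path, index=False)


def read_sites_csv(path) -> pd.DataFrame:
    sites = pd.read_csv(path)
    missing = [c for c in SITE_BASE_COLUMNS if c not in sites.columns]
    if missing:
        raise ValueError(f"site table missing required columns: {missing}")
    return sites
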