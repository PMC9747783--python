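"""Regular geographic grids and spherical cell areas.

All analyses run on a regular longitude/latitude grid (default resolution
0.5°) with half-open cells [west, east) x [south, north).  Cell (0, 0) sits at
the grid's south-west corner; flattened cell ids are ``iy * n_lon + ix``
(row-major, south to north).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class GridSpec:
    """A regular lon/lat grid.

    Parameters
    ----------
    lon_min, lon_max, lat_min, lat_max : float
        Grid bounds in decimal degrees.  Longitude convention is
        [-180, 180); latitudes must lie in [-90, 90].
    resolution : float
        Cell size in degrees (square cells), default 0.5.
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    resolution: float = 0.5

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if not (-90.0 <= self.lat_min < self.lat_max <= 90.0):
            raise ValueError("latitudes must satisfy -90 <= lat_min < lat_max <= 90")
        if not self.lon_min < self.lon_max:
            raise ValueError("lon_min must be < lon_max")
        for span, name in ((self.lon_max - self.lon_min, "longitude"),
                           (self.lat_max - self.lat_min, "latitude")):
            n = span / self.resolution
            if abs(n - round(n)) > 1e-9:
                raise ValueError(f"{name} span is not an integer number of cells")
        if self.n_cells == 0:
            raise ValueError("degenerate grid: zero cells")

    @property
    def n_lon(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.resolution))

    @property
    def n_lat(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.resolution))

    @property
    def n_cells(self) -> int:
        return self.n_lon * self.n_lat

    @property
    def shape(self) -> tuple[int, int]:
        """(n_lat, n_lon) — raster-style row/column shape."""
        return (self.n_lat, self.n_lon)

    def lon_edges(self) -> np.ndarray:
        return self.lon_min + self.resolution * np.arange(self.n_lon + 1)

    def lat_edges(self) -> np.ndarray:
        return self.lat_min + self.resolution * np.arange(self.n_lat + 1)

    def centroids(self) -> np.ndarray:
        """(n_cells, 2) array of (lon, lat) cell centroids, row-major."""
        lons = self.lon_edges()[:-1] + self.resolution / 2.0
        lats = self.lat_edges()[:-1] + self.resolution / 2.0
        gx, gy = np.meshgrid(lons, lats)
        return np.column_stack([gx.ravel(), gy.ravel()])

    def cell_bounds(self, cell_id: int) -> tuple[float, float, float, float]:
        """(west, south, east, north) of one cell."""
        iy, ix = divmod(int(cell_id), self.n_lon)
        w = self.lon_min + ix * self.resolution
        s = self.lat_min + iy * self.resolution
        return (w, s, w + self.resolution, s + self.resolution)

    def cell_areas(self, radius: float = EARTH_RADIUS_KM) -> np.ndarray:
        """Per-cell spherical areas in km², flattened row-major."""
        lat_e = self.lat_edges()
        band = cell_area(lat_e[:-1], lat_e[1:], self.resolution, radius)
        return np.repeat(band, self.n_lon)


def cell_area(lat_south, lat_north, dlon: float, radius: float = EARTH_RADIUS_KM):
    """Area of a spherical lon/lat rectangle in km².

    Uses the exact spherical formula R² · Δλ · (sin φ_N − sin φ_S); equal-angle
    cells therefore shrink toward the poles, which is why area weighting is
    required on 0.5° grids.

    Parameters are in degrees, ``radius`` in km.  Accepts scalars or arrays.
    """
    lat_south = np.asarray(lat_south, dtype=float)
    lat_north = np.asarray(lat_north, dtype=float)
    if np.any(lat_south >= lat_north):
        raise ValueError("lat_south must be < lat_north")
    if np.any(lat_south < -90.0) or np.any(lat_north > 90.0):
        raise ValueError("latitudes outside [-90, 90]")
    if dlon <= 0:
        raise ValueError("dlon must be positive")
    dl = np.deg2rad(dlon)
    out = radius * radius * dl * (np.sin(np.deg2rad(lat_north)) - np.sin(np.deg2rad(lat_south)))
    return out if out.ndim else float(out)


def great_circle_distance(coords: np.ndarray, radius: float = EARTH_RADIUS_KM) -> np.ndarray:
    """Pairwise great-circle distance matrix (km) from (n, 2) lon/lat degrees.

    Haversine formula; symmetric with a zero diagonal.
    """
    lon = np.deg2rad(coords[:, 0])
    lat = np.deg2rad(coords[:, 1])
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    return 2.0 * radius * np.arcsin(np.sqrt(a))
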