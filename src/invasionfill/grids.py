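"""Gridded world container: climate layers, land mask, realm and admin-unit partitions.

The analysis grid is a regular lon/lat lattice (10 arc-minute cells by default).
Row 0 is the southernmost row; cell (row, col) covers the half-open box
[lon0 + col*cs, lon0 + (col+1)*cs) x [lat0 + row*cs, lat0 + (row+1)*cs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: order of the climate layers in :attr:`ClimateGrid.climate`
CLIMATE_VARS = ("temp_coldest_month", "temp_warmest_month", "annual_precip")

EARTH_KM_PER_DEG = 111.32  # at the equator


@dataclass
class ClimateGrid:
    """A lon/lat raster world with climate, land, realm and admin-unit layers.

    Attributes
    ----------
    climate : (3, nrows, ncols) float array
        Layers in :data:`CLIMATE_VARS` order: mean temperature of the coldest
        month, mean temperature of the warmest month (deg C), total annual
        precipitation (mm).
    land : (nrows, ncols) bool array
    realm : (nrows, ncols) int array
        Biogeographic realm id per cell; 0 on sea cells.
    admin : (nrows, ncols) int array
        Administrative unit id per cell; 0 on sea cells.
    cell_size : float
        Cell edge length in degrees.
    origin : (float, float)
        (lon, lat) of the south-west corner of cell (0, 0).
    """

    climate: np.ndarray
    land: np.ndarray
    realm: np.ndarray
    admin: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.climate.ndim != 3 or self.climate.shape[0] != len(CLIMATE_VARS):
            raise ValueError("climate must be (3, nrows, ncols)")
        if self.land.shape != self.shape or self.realm.shape != self.shape:
            raise ValueError("layer shapes disagree")
        if np.any((self.realm > 0) != self.land) or np.any((self.admin > 0) != self.land):
            raise ValueError("every land cell needs a realm and admin id; sea cells none")

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.climate.shape[1:]

    @property
    def nrows(self) -> int:
        return self.shape[0]

    @property
    def ncols(self) -> int:
        return self.shape[1]

    def cell_of(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to 0-based (row, col) by floor division (half-open cells).

        Points outside the lattice get index -1.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((lat - self.origin[1]) / self.cell_size).astype(int)
        bad = (col < 0) | (col >= self.ncols) | (row < 0) | (row >= self.nrows)
        col = np.where(bad, -1, col)
        row = np.where(bad, -1, row)
        return row, col

    def cell_centre(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lon = self.origin[0] + (np.asarray(col) + 0.5) * self.cell_size
        lat = self.origin[1] + (np.asarray(row) + 0.5) * self.cell_size
        return lon, lat

    def cell_area_km2(self) -> np.ndarray:
        """Per-cell area, (cell width at the equator)^2 * cos(latitude of centre)."""
        lat = self.origin[1] + (np.arange(self.nrows) + 0.5) * self.cell_size
        area_row = (EARTH_KM_PER_DEG * self.cell_size) ** 2 * np.cos(np.radians(lat))
        return np.repeat(area_row[:, None], self.ncols, axis=1)

    # -- convenience --------------------------------------------------------

    def realm_mask(self, realm_id: int) -> np.ndarray:
        return self.land & (self.realm == realm_id)

    def realm_climate(self, realm_id: int) -> np.ndarray:
        """Climate matrix (n_cells, 3) of the realm's land cells (row-major order)."""
        m = self.realm_mask(realm_id)
        return self.climate[:, m].T

    def realm_cells(self, realm_id: int) -> tuple[np.ndarray, np.ndarray]:
        return np.nonzero(self.realm_mask(realm_id))

    def climate_at(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        """Gridded climate (n, 3) at point locations; NaN rows off-lattice or at sea."""
        row, col = self.cell_of(lon, lat)
        out = np.full((row.size, len(CLIMATE_VARS)), np.nan)
        ok = (row >= 0) & self.land[np.clip(row, 0, None), np.clip(col, 0, None)]
        out[ok] = self.climate[:, row[ok], col[ok]].T
        return out


# -- plain-text raster IO (Arc/Info ASCII grid) -----------------------------

def write_ascii_grid(path: str | Path, array: np.ndarray, cell_size: float,
                     origin: tuple[float, float] = (0.0, 0.0),
                     nodata: float = -9999.0) -> None:
    """Write a raster as an ESRI ASCII grid (text format, row 0 printed last)."""
    a = np.asarray(array, dtype=float)
    header = (
        f"ncols {a.shape[1]}\nnrows {a.shape[0]}\n"
        f"xllcorner {origin[0]}\nyllcorner {origin[1]}\n"
        f"cellsize {cell_size}\nNODATA_value {nodata}\n"
    )
    body = np.where(np.isfinite(a), a, nodata)[::-1]  # north-up on disk
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.6g")


def write_unit_geojson(path: str | Path, grid: "ClimateGrid", layer: str = "admin") -> None:
    """Write realm or admin-unit outlines as a GeoJSON FeatureCollection.

    Each unit's polygon is the union of its cells' bounding boxes.
    """
    import json

    from shapely.geometry import box, mapping
    from shapely.ops import unary_union

    ids = getattr(grid, layer)
    features = []
    for uid in np.unique(ids[ids > 0]):
        rows, cols = np.nonzero(ids == uid)
        cells = [box(grid.origin[0] + c * grid.cell_size,
                     grid.origin[1] + r * grid.cell_size,
                     grid.origin[0] + (c + 1) * grid.cell_size,
                     grid.origin[1] + (r + 1) * grid.cell_size)
                 for r, c in zip(rows, cols)]
        geom = unary_union(cells)
        features.append({"type": "Feature", "properties": {layer: int(uid)},
                         "geometry": mapping(geom)})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float, tuple[float, float]]:
    """Read an ESRI ASCII grid; returns (array south-up, cell_size, origin)."""
    with open(path) as fh:
        hdr = {}
        for _ in range(6):
            key, val = fh.readline().split()
            hdr[key.lower()] = float(val)
        body = np.loadtxt(fh)
    body = np.atleast_2d(body)[::-1].copy()
    body[body == hdr["nodata_value"]] = np.nan
    return body, hdr["cellsize"], (hdr["xllcorner"], hdr["yllcorner"])
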