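"""Naturalised range polygons, range/niche filling, threat maps, effort adjustment.

The occupied naturalised range of a species is the union of per-admin-unit
convex hulls around its naturalised occurrences.  Range filling is the
area-weighted proportion of the climatically suitable (potential) range that
this union covers; the unoccupied remainder is the invasion deficit.  Threat
maps count, per grid cell, how many species could still spread there; the
recording-effort adjustment rescales those counts by the reciprocal of the
local detection probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, Point
from shapely.ops import unary_union

from .grids import ClimateGrid
from .niche import PotentialRange
from .synthetic_world import OccurrenceSet

__all__ = [
    "RangePolygonSet", "ThreatMap", "range_polygons", "covered_mask",
    "range_filling", "niche_filling", "threat_map", "effort_adjust",
    "median_range_filling",
]


@dataclass
class RangePolygonSet:
    """Per-admin-unit convex hulls of a species' naturalised occurrences."""

    species: str
    realm: int
    hulls: dict  # admin id -> shapely geometry
    union: shapely.Geometry
    occupied_area_km2: float


def range_polygons(occs, grid: ClimateGrid, realm: int,
                   buffer_radius: float | None = None) -> RangePolygonSet:
    """Convex hull per admin unit around naturalised occurrences, dissolved.

    Hulls never bridge admin units.  Degenerate units (one or two points, or
    collinear points) are buffered to half a grid cell so their occupancy is
    non-zero.  Occupied area is the cos-latitude-weighted area of the realm
    cells whose centre falls in the union.
    """
    if isinstance(occs, OccurrenceSet):
        rec = occs.records
        species = occs.species
    else:
        rec = occs
        species = str(rec["species"].iloc[0]) if "species" in rec else "species"
    rec = rec[rec["status"] == "naturalised"]
    row, col = grid.cell_of(rec["lon"].to_numpy(), rec["lat"].to_numpy())
    in_realm = (row >= 0) & (grid.realm[np.clip(row, 0, None), np.clip(col, 0, None)] == realm)
    rec = rec[in_realm]
    if rec.empty:
        raise ValueError("no naturalised occurrences in the realm")
    admin = grid.admin[row[in_realm], col[in_realm]]

    radius = grid.cell_size / 2.0 if buffer_radius is None else buffer_radius
    hulls = {}
    for unit in np.unique(admin):
        pts = rec[["lon", "lat"]].to_numpy()[admin == unit]
        hull = MultiPoint([Point(xy) for xy in pts]).convex_hull
        if hull.area == 0:  # 1-2 points or collinear
            hull = hull.buffer(radius)
        hulls[int(unit)] = hull
    union = unary_union(list(hulls.values()))

    poly = RangePolygonSet(species=species, realm=realm, hulls=hulls,
                           union=union, occupied_area_km2=0.0)
    cov = covered_mask(poly, grid) & grid.realm_mask(realm)
    poly.occupied_area_km2 = float(grid.cell_area_km2()[cov].sum())
    return poly


def covered_mask(polygons: RangePolygonSet, grid: ClimateGrid) -> np.ndarray:
    """Cells whose centre lies inside the polygon union."""
    rows, cols = np.nonzero(grid.land)
    lon, lat = grid.cell_centre(rows, cols)
    shapely.prepare(polygons.union)
    inside = shapely.contains_xy(polygons.union, lon, lat)
    m = np.zeros(grid.shape, dtype=bool)
    m[rows[inside], cols[inside]] = True
    return m


def range_filling(potential: PotentialRange, polygons: RangePolygonSet,
                  grid: ClimateGrid) -> float:
    """Proportion of the climatically suitable area filled by the range polygons.

    Area-weighted by cell; a cell counts as filled when its centre lies inside
    the dissolved polygon union.
    """
    if potential.n_cells == 0 or potential.area_km2 <= 0:
        raise ValueError("potential range has zero area")
    area = grid.cell_area_km2()
    pot = potential.mask(grid)
    cov = covered_mask(polygons, grid)
    return float(area[pot & cov].sum() / area[pot].sum())


def niche_filling(native_niche: np.ndarray, occs, space, grid: ClimateGrid) -> float:
    """Fraction of native-niche analogue PCA cells holding a naturalised record."""
    from .niche import analogue_cells

    cells = native_niche & analogue_cells(space)
    total = int(cells.sum())
    if total == 0:
        raise ValueError("empty native niche")
    rec = occs.records if isinstance(occs, OccurrenceSet) else occs
    rec = rec[rec["status"] == "naturalised"]
    clim = grid.climate_at(rec["lon"].to_numpy(), rec["lat"].to_numpy())
    clim = clim[np.isfinite(clim).all(axis=1)]
    ix, iy = space.bin_of(space.scores(clim))
    ok = (ix >= 0) & (iy >= 0)
    occ = np.zeros_like(cells)
    occ[ix[ok], iy[ok]] = True
    return float((cells & occ).sum() / total)


# -- threat maps ------------------------------------------------------------

@dataclass
class ThreatMap:
    """Per-cell count of species whose unoccupied potential range includes the cell."""

    counts: np.ndarray
    adjusted: np.ndarray | None = None


def threat_map(records: list[tuple[PotentialRange, RangePolygonSet | None]],
               grid: ClimateGrid, exclude_occupied: bool = True) -> ThreatMap:
    """Stack species-level spread potential into a per-cell count.

    For each (potential range, occupied polygons) pair, every suitable cell
    outside the occupied polygons increments the count (``exclude_occupied``
    False counts all suitable cells instead).
    """
    counts = np.zeros(grid.shape, dtype=int)
    for potential, polygons in records:
        m = potential.mask(grid)
        if exclude_occupied and polygons is not None:
            m &= ~covered_mask(polygons, grid)
        counts += m
    return ThreatMap(counts=counts)


def _nearest_neighbour_resample(src: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    src = np.asarray(src, dtype=float)
    ri = np.minimum((np.arange(shape[0]) + 0.5) * src.shape[0] // shape[0], src.shape[0] - 1)
    ci = np.minimum((np.arange(shape[1]) + 0.5) * src.shape[1] // shape[1], src.shape[1] - 1)
    return src[np.ix_(ri.astype(int), ci.astype(int))]


def effort_adjust(tmap: ThreatMap, detection: np.ndarray,
                  floor: float = 1e-4) -> ThreatMap:
    """Rescale threat counts by the reciprocal of detection probability.

    ``adjusted = counts / max(detection, floor)``; the default floor of 0.01%
    caps the inflation at x10,000.  A detection raster at a different
    resolution is resampled to the analysis grid by nearest neighbour.
    """
    det = np.asarray(detection, dtype=float)
    if np.any((det < 0) | (det > 1)):
        raise ValueError("detection probabilities must lie in [0, 1]")
    if det.shape != tmap.counts.shape:
        det = _nearest_neighbour_resample(det, tmap.counts.shape)
    adjusted = tmap.counts / np.maximum(det, floor)
    return ThreatMap(counts=tmap.counts, adjusted=adjusted)


def median_range_filling(table: pd.DataFrame, taxon: str | None = None,
                         filling_col: str = "filling", percent: bool = True) -> float:
    """Median range filling over establishment events, optionally one taxon.

    Accepts a derived-data table with one row per species x naturalised-realm
    event; returns the median as a percentage by default.
    """
    df = table
    if taxon is not None:
        df = df[df["taxon"] == taxon]
    if df.empty:
        raise ValueError("no establishment events selected")
    med = float(df[filling_col].median())
    return 100.0 * med if percent else med
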