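"""Occurrence cleaning, status classification, and establishment-event splitting.

Raw point records are filtered in three ordered stages (off-shore points,
coordinates too coarse for the 10 arc-minute grid, points at country/state
centroids), classified native or naturalised against per-admin-unit
checklists, and split into establishment records: one species in one
naturalised realm, kept only when it occupies at least ``min_cells`` grid
cells in both its native and that naturalised range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import ClimateGrid
from .synthetic_world import OccurrenceSet

__all__ = ["EstablishmentRecord", "clean_occurrences", "classify_and_split"]

#: coordinate precision finer than this (degrees) is required; 10 arc-minutes
PRECISION_LIMIT_DEG = 1.0 / 6.0
#: equivalent limit for an explicit uncertainty radius
PRECISION_LIMIT_KM = 18.5


@dataclass
class EstablishmentRecord:
    """One species x naturalised-realm event."""

    species: str
    naturalised_realm: int
    native_realms: tuple[int, ...]
    n_cells: int  # occupied 10-min cells in the naturalised realm
    introduction_year: int | None = None
    taxon: str | None = None

    def __post_init__(self) -> None:
        if self.naturalised_realm in self.native_realms:
            raise ValueError("naturalised realm cannot be a native realm")


def clean_occurrences(occs: OccurrenceSet, grid: ClimateGrid,
                      centroids: np.ndarray | None = None,
                      centroid_tol: float | None = None) -> OccurrenceSet:
    """Apply the three cleaning filters in order; idempotent.

    1. drop points off-shore (outside the lattice or on sea cells);
    2. drop points whose ``precision_deg`` is coarser than 10 arc-minutes or
       whose ``uncertainty_km`` exceeds 18.5 km (columns optional);
    3. drop points within half a grid cell of any supplied centroid
       (``centroids`` is an (n, 2) array of lon, lat).
    """
    rec = occs.records
    if rec.empty:
        return OccurrenceSet(occs.species, rec.copy(), occs.too_few_suitable)

    row, col = grid.cell_of(rec["lon"].to_numpy(), rec["lat"].to_numpy())
    on_land = (row >= 0) & grid.land[np.clip(row, 0, None), np.clip(col, 0, None)]
    rec = rec[on_land]

    if "precision_deg" in rec.columns:
        rec = rec[~(rec["precision_deg"].fillna(0.0) > PRECISION_LIMIT_DEG)]
    if "uncertainty_km" in rec.columns:
        rec = rec[~(rec["uncertainty_km"].fillna(0.0) > PRECISION_LIMIT_KM)]

    if centroids is not None and len(centroids):
        tol = grid.cell_size / 2.0 if centroid_tol is None else centroid_tol
        pts = rec[["lon", "lat"]].to_numpy()
        cen = np.asarray(centroids, dtype=float).reshape(-1, 2)
        d2 = ((pts[:, None, :] - cen[None, :, :]) ** 2).sum(axis=2)
        rec = rec[np.sqrt(d2).min(axis=1) > tol]

    return OccurrenceSet(occs.species, rec.reset_index(drop=True), occs.too_few_suitable)


def _occupied_cells(rec: pd.DataFrame, grid: ClimateGrid) -> set[tuple[int, int]]:
    row, col = grid.cell_of(rec["lon"].to_numpy(), rec["lat"].to_numpy())
    return set(zip(row.tolist(), col.tolist()))


def classify_and_split(occs: OccurrenceSet, checklist: pd.DataFrame,
                       grid: ClimateGrid, min_cells: int = 5,
                       drop_species_entirely: bool = False,
                       introduction_years: dict[int, int] | None = None,
                       taxon: str | None = None) -> list[EstablishmentRecord]:
    """Classify points via checklists and split into establishment records.

    ``checklist`` has columns (admin, species, status); points whose
    (admin unit, species) pair is not validated there are discarded.  A species
    native and naturalised in the same realm loses that realm's record (or all
    records when ``drop_species_entirely``).  Species occupying fewer than
    ``min_cells`` cells in the native range, or in a given naturalised realm,
    yield no record (for that realm).  ``introduction_years`` maps naturalised
    realm id to first-record year.
    """
    rec = occs.records.copy()
    row, col = grid.cell_of(rec["lon"].to_numpy(), rec["lat"].to_numpy())
    if np.any(row < 0):
        raise ValueError("points outside the grid; run clean_occurrences first")
    admin = grid.admin[row, col]
    if np.any(admin <= 0):
        raise ValueError("occurrence on a cell without an admin unit")
    rec["admin"] = admin
    rec["realm"] = grid.realm[row, col]

    chk = checklist[checklist["species"] == occs.species]
    status_map = dict(zip(chk["admin"].astype(int), chk["status"]))
    rec["status"] = rec["admin"].map(status_map)
    rec = rec.dropna(subset=["status"])  # unvalidated points discarded

    native = rec[rec["status"] == "native"]
    natur = rec[rec["status"] == "naturalised"]
    native_realms = tuple(sorted(set(native["realm"].tolist())))
    if len(_occupied_cells(native, grid)) < min_cells:
        return []

    conflict = any(r in native_realms for r in set(natur["realm"]))
    records: list[EstablishmentRecord] = []
    for realm_id, grp in natur.groupby("realm"):
        realm_id = int(realm_id)
        if realm_id in native_realms:
            continue  # same-realm native+naturalised pair dropped
        if drop_species_entirely and conflict:
            continue
        n_cells = len(_occupied_cells(grp, grid))
        if n_cells < min_cells:
            continue
        year = (introduction_years or {}).get(realm_id)
        records.append(EstablishmentRecord(
            species=occs.species, naturalised_realm=realm_id,
            native_realms=native_realms, n_cells=n_cells,
            introduction_year=year, taxon=taxon))
    return records
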