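"""Synthetic world generator: climate fields, realms, species, regression data.

Everything downstream of raw data collation can be exercised on worlds built
here: spatially autocorrelated climate rasters partitioned into contiguous
biogeographic realms and administrative units, species with known Gaussian
climate niches and a known fraction of their suitable introduced area filled,
and beta-regression datasets drawn from the exact hierarchical model the
statistical module fits.  Every generator is fully determined by its seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit

from .grids import CLIMATE_VARS, ClimateGrid
from .predictors import PredictorTable

__all__ = [
    "WorldConfig", "SpeciesTruth", "OccurrenceSet",
    "make_world", "make_species", "make_regression_data",
    "make_checklist", "niche_density", "true_suitable_mask",
]

#: density below max/1000 is treated as zero, matching the niche model's rule
DENSITY_FLOOR_RATIO = 1e-3


@dataclass
class WorldConfig:
    """Parameters of a synthetic world.

    Climate layers are Gaussian random fields: white noise convolved with a
    Gaussian kernel (``corr_length`` in cells) and rescaled to the requested
    mean and variance; the coldest-month layer carries a latitudinal gradient
    and the warmest-month layer tracks it with a configurable offset, so the
    three variables have an effectively two-dimensional structure like real
    terrestrial climate.
    """

    nrows: int = 60
    ncols: int = 60
    cell_size: float = 1.0 / 6.0  # degrees; 10 arc-minutes
    n_realms: int = 2
    n_admin_per_realm: int = 100  # laid out as a near-square grid of blocks
    climate_mean: tuple[float, float, float] = (0.0, 18.0, 1000.0)
    climate_sd: tuple[float, float, float] = (8.0, 3.0, 400.0)
    corr_length: tuple[float, float, float] = (6.0, 4.0, 5.0)  # cells
    lat_gradient: float = 0.0  # deg C per degree latitude on the coldest month
    sea_border: int = 1  # ring of sea cells around the lattice
    seed: int = 0

    def validate(self) -> None:
        if self.nrows < 20 or self.ncols < 20:
            raise ValueError("grid must be at least 20 x 20")
        if any(c <= 0 for c in self.corr_length):
            raise ValueError("correlation lengths must be positive")
        if self.n_realms < 1 or self.n_admin_per_realm < 1:
            raise ValueError("need at least one realm and one admin unit")
        if 2 * self.sea_border >= min(self.nrows, self.ncols):
            raise ValueError("sea border swallows the whole grid")


@dataclass
class SpeciesTruth:
    """Ground truth for one synthetic species.

    The climate niche is a bivariate Gaussian density over two raw-unit
    climate variables (``niche_vars`` indexes into the climate layers; the
    default is coldest-month temperature and annual precipitation).
    ``f_true`` is the fraction of the climatically suitable introduced-realm
    area the species has actually filled.
    """

    species: str
    niche_centre: np.ndarray
    niche_cov: np.ndarray
    native_realm: int
    introduced_realm: int
    f_true: float = 0.5
    introduction_year: int = 1900
    traits: dict = field(default_factory=dict)
    niche_vars: tuple[int, ...] = (0, 2)

    def __post_init__(self) -> None:
        if self.native_realm == self.introduced_realm:
            raise ValueError("native and introduced realm must differ")
        if not 0.0 <= self.f_true <= 1.0:
            raise ValueError("f_true must lie in [0, 1]")


@dataclass
class OccurrenceSet:
    """Occurrence records for one species: lon, lat, status, admin unit."""

    species: str
    records: pd.DataFrame  # columns: lon, lat, status, admin
    too_few_suitable: bool = False  # < 5 suitable introduced cells

    def to_gbif_csv(self, path: str | Path) -> None:
        out = pd.DataFrame({
            "species": self.species,
            "decimalLongitude": self.records["lon"].round(6),
            "decimalLatitude": self.records["lat"].round(6),
            "status": self.records["status"],
        })
        out.to_csv(path, index=False, lineterminator="\n")


# -- world ------------------------------------------------------------------

def _gaussian_field(shape, corr_length, rng) -> np.ndarray:
    """Unit-variance Gaussian random field by Gaussian smoothing of white noise."""
    noise = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(noise, sigma=corr_length, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


def make_world(config: WorldConfig) -> ClimateGrid:
    """Build the synthetic climate grid with realm and admin partitions.

    Realms are contiguous vertical bands of land; each realm is split into
    contiguous horizontal admin-unit bands.  Deterministic per seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    shape = (config.nrows, config.ncols)
    mu, sd, cl = config.climate_mean, config.climate_sd, config.corr_length

    t_cold = mu[0] + sd[0] * _gaussian_field(shape, cl[0], rng)
    if config.lat_gradient:
        lat = (np.arange(config.nrows) + 0.5) * config.cell_size
        t_cold += config.lat_gradient * (lat - lat.mean())[:, None]
    t_warm = t_cold + mu[1] + sd[1] * _gaussian_field(shape, cl[1], rng)
    precip = np.clip(mu[2] + sd[2] * _gaussian_field(shape, cl[2], rng), 0.0, None)
    climate = np.stack([t_cold, t_warm, precip])

    land = np.ones(shape, dtype=bool)
    b = config.sea_border
    if b > 0:
        land[:b, :] = land[-b:, :] = False
        land[:, :b] = land[:, -b:] = False

    realm = np.zeros(shape, dtype=int)
    admin = np.zeros(shape, dtype=int)
    land_cols = np.nonzero(land.any(axis=0))[0]
    col_bands = np.array_split(land_cols, config.n_realms)
    land_rows = np.nonzero(land.any(axis=1))[0]
    # admin units tile each realm with a near-square grid of contiguous blocks
    a_rows = max(1, int(np.round(np.sqrt(config.n_admin_per_realm))))
    a_cols = int(np.ceil(config.n_admin_per_realm / a_rows))
    row_bands = np.array_split(land_rows, a_rows)
    for r, cols in enumerate(col_bands, start=1):
        cmask = np.zeros(shape, dtype=bool)
        cmask[:, cols] = True
        realm[land & cmask] = r
        sub_cols = np.array_split(cols, a_cols)
        unit = (r - 1) * a_rows * a_cols
        for rows in row_bands:
            for ccols in sub_cols:
                unit += 1
                amask = np.zeros(shape, dtype=bool)
                amask[np.ix_(rows, ccols)] = True
                admin[land & amask] = unit
    return ClimateGrid(climate=climate, land=land, realm=realm, admin=admin,
                       cell_size=config.cell_size)


# -- species ----------------------------------------------------------------

def niche_density(grid: ClimateGrid, truth: SpeciesTruth) -> np.ndarray:
    """True (unnormalised) Gaussian niche density evaluated at every cell."""
    clim = grid.climate.reshape(len(CLIMATE_VARS), -1).T[:, list(truth.niche_vars)]
    diff = clim - truth.niche_centre
    prec = np.linalg.inv(truth.niche_cov)
    maha2 = np.einsum("ij,jk,ik->i", diff, prec, diff)
    dens = np.exp(-0.5 * maha2)
    dens = dens.reshape(grid.shape)
    dens[~grid.land] = 0.0
    return dens


def true_suitable_mask(grid: ClimateGrid, truth: SpeciesTruth, realm: int | None = None) -> np.ndarray:
    """Climatically suitable cells of a realm under the species' true niche.

    Suitability uses the same convention as the niche model: density at least
    one thousandth of the realm's maximum cell density.
    """
    realm = truth.introduced_realm if realm is None else realm
    dens = niche_density(grid, truth)
    mask = grid.realm_mask(realm)
    if not mask.any():
        raise ValueError(f"realm {realm} has no land cells")
    dmax = dens[mask].max()
    return mask & (dens >= DENSITY_FLOOR_RATIO * dmax) & (dens > 0)


def _region_grow(suitable: np.ndarray, n_target: int, rng) -> np.ndarray:
    """Contiguous subset of the suitable mask grown from a random seed cell.

    Rook-neighbour breadth-first growth from a random introduction point; if a
    connected component is exhausted before the target count, growth restarts
    at another random unvisited suitable cell (disconnected suitable patches).
    """
    occupied = np.zeros_like(suitable)
    order = [tuple(c) for c in np.argwhere(suitable)]
    rng.shuffle(order)
    pool = set(order)
    todo = n_target
    while todo > 0 and pool:
        start = next(c for c in order if c in pool)
        frontier = [start]
        while frontier and todo > 0:
            cell = frontier.pop(0)
            if cell not in pool:
                continue
            pool.discard(cell)
            occupied[cell] = True
            todo -= 1
            r, c = cell
            for nb in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if nb in pool:
                    frontier.append(nb)
    return occupied


def make_species(grid: ClimateGrid, truth: SpeciesTruth,
                 n_native: int = 100, n_introduced: int = 30,
                 rng: np.random.Generator | int | None = None) -> OccurrenceSet:
    """Sample occurrences for one species.

    Native records are drawn from native-realm cells with probability
    proportional to the true niche density, jittered inside the cell.
    Introduced records cover a spatially contiguous region grown from a random
    introduction point over ~``f_true`` of the suitable introduced-realm cells;
    at least one record is placed in every occupied cell (so ``f_true = 1``
    saturates the suitable area), with extra records to reach ``n_introduced``.
    """
    rng = np.random.default_rng(rng)
    dens = niche_density(grid, truth)
    nat_mask = grid.realm_mask(truth.native_realm)
    if dens[nat_mask].sum() <= 0:
        raise ValueError("niche centre has no support in the native realm")

    def _points_in_cells(rows, cols, n_extra=0):
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        lon, lat = grid.cell_centre(rows, cols)
        jit = (rng.random((2, rows.size)) - 0.5) * grid.cell_size * 0.9
        return lon + jit[0], lat + jit[1]

    # native: weighted cell sampling with replacement
    nr, nc = np.nonzero(nat_mask)
    w = dens[nr, nc]
    pick = rng.choice(nr.size, size=n_native, p=w / w.sum())
    lon_n, lat_n = _points_in_cells(nr[pick], nc[pick])

    # introduced: contiguous occupancy of ~f_true of the suitable cells
    suitable = true_suitable_mask(grid, truth)
    n_suit = int(suitable.sum())
    flag = n_suit < 5
    if flag:
        warnings.warn(f"{truth.species}: only {n_suit} suitable introduced cells")
    n_occ = int(np.round(truth.f_true * n_suit))
    if truth.f_true > 0 and n_suit > 0:
        n_occ = max(n_occ, 1)
    occupied = _region_grow(suitable, n_occ, rng)
    orows, ocols = np.nonzero(occupied)
    if orows.size:
        lon_i, lat_i = _points_in_cells(orows, ocols)
        extra = n_introduced - orows.size
        if extra > 0:
            pick = rng.choice(orows.size, size=extra)
            lon_e, lat_e = _points_in_cells(orows[pick], ocols[pick])
            lon_i = np.concatenate([lon_i, lon_e])
            lat_i = np.concatenate([lat_i, lat_e])
    else:
        lon_i = lat_i = np.empty(0)

    lon = np.concatenate([lon_n, lon_i])
    lat = np.concatenate([lat_n, lat_i])
    status = ["native"] * lon_n.size + ["naturalised"] * lon_i.size
    row, col = grid.cell_of(lon, lat)
    rec = pd.DataFrame({
        "lon": lon, "lat": lat, "status": status,
        "admin": grid.admin[row, col],
    })
    return OccurrenceSet(species=truth.species, records=rec, too_few_suitable=flag)


def make_checklist(occ_sets: list[OccurrenceSet]) -> pd.DataFrame:
    """Admin-unit status checklist consistent with the generated occurrences.

    One row per (admin unit, species) with the species' status there; this is
    the validation table the occurrence pipeline classifies against.
    """
    rows = []
    for occ in occ_sets:
        grp = occ.records.groupby(["admin", "status"]).size().reset_index()
        for _, row in grp.iterrows():
            rows.append({"admin": int(row["admin"]), "species": occ.species,
                         "status": row["status"]})
    return pd.DataFrame(rows, columns=["admin", "species", "status"]).drop_duplicates()


# -- regression data --------------------------------------------------------

def make_regression_data(coefs: dict[str, float], realm_sd: float | dict[str, float] = 0.3,
                         phi: float = 15.0, n: int = 5000, n_realms: int = 6,
                         seed: int | np.random.Generator = 0,
                         intercept: float = 0.0) -> PredictorTable:
    """Simulate establishment events from the hierarchical beta-logit model.

    ``logit(mu) = intercept + sum_k beta_k x_k + u_realm (+ v_{k,realm} x_k)``
    with ``u_r ~ Normal(0, sd)`` and the response drawn
    ``Beta(mu * phi, (1 - mu) * phi)``.  Covariates are standard normal.
    ``realm_sd`` is a scalar (intercept spread only) or a map from
    ``"intercept"`` / covariate name to the spread of that term's
    realm-varying effects.
    """
    if not np.all(np.isfinite(list(coefs.values()) + [intercept])):
        raise ValueError("coefficients must be finite")
    if phi <= 0:
        raise ValueError("phi must be positive")
    if n < 10:
        raise ValueError("need at least 10 observations")
    rng = np.random.default_rng(seed)
    if not isinstance(realm_sd, dict):
        realm_sd = {"intercept": float(realm_sd)}

    realm = rng.integers(0, n_realms, size=n)
    eta = np.full(n, float(intercept))
    u = rng.normal(0.0, realm_sd.get("intercept", 0.0), size=n_realms)
    eta += u[realm]
    X = {}
    for name, beta in coefs.items():
        x = rng.standard_normal(n)
        X[name] = x
        slope = beta + rng.normal(0.0, realm_sd.get(name, 0.0), size=n_realms)[realm]
        eta += slope * x
    mu = expit(eta)
    y = rng.beta(mu * phi, (1.0 - mu) * phi)
    y = np.clip(y, 1e-9, 1.0 - 1e-9)  # keep the response strictly inside (0,1)

    df = pd.DataFrame(X)
    df["realm"] = [f"realm_{r + 1}" for r in realm]
    df["filling"] = y
    return PredictorTable(data=df, response="filling", group="realm",
                          continuous=tuple(coefs), categorical=())
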