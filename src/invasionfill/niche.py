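"""Climate-matching niche model in a kernel-smoothed PCA climate space.

The climate of the native and naturalised biogeographic realms is pooled,
precipitation log-transformed, all variables scaled to mean 0 / sd 1, and
reduced to two principal-component axes discretised into a 100 x 100 grid.
Native occurrence records are kernel-smoothed over this climate space with a
bivariate normal kernel (ad hoc bandwidth), divided by the kernel-smoothed
climate availability of the realm, and thresholded: corrected densities below
one thousandth of the maximum are treated as zero.  The native-niche cells,
restricted to analogue climate (present in both realms), are projected back
onto the naturalised realm's geography to give the potential naturalised
range.  Cross-validation splits the native data 80/20 five times and scores
true-presence accuracy and TSS against repeated pseudo-absence draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .grids import ClimateGrid
from .synthetic_world import OccurrenceSet

__all__ = [
    "ClimateSpace", "DensityGrid", "PotentialRange", "CVReport",
    "build_climate_space", "occurrence_density", "niche_cells",
    "analogue_cells", "project_range", "potential_range", "tss", "crossvalidate",
]

NBINS = 100
DENSITY_FLOOR_RATIO = 1e-3


@dataclass
class ClimateSpace:
    """Fitted two-axis ordination of the pooled realm climate.

    Scaling parameters, PCA loadings, the exact bounds of the 100 x 100
    discretisation, and per-PCA-cell availability counts for the native and
    introduced realm are all frozen at build time.
    """

    mean_: np.ndarray          # per-variable mean after the precip log
    sd_: np.ndarray            # per-variable sd after the precip log
    components_: np.ndarray    # (2, 3) PCA loadings
    explained_variance_ratio_: np.ndarray
    bounds: np.ndarray         # (2, 2): [[x_lo, x_hi], [y_lo, y_hi]]
    native_realm: int
    introduced_realm: int
    avail_native: np.ndarray   # (100, 100) cell counts
    avail_intro: np.ndarray
    log_precip: bool = True

    # -- mapping -----------------------------------------------------------

    def scale_climate(self, clim: np.ndarray) -> np.ndarray:
        clim = np.asarray(clim, dtype=float).copy()
        if self.log_precip:
            clim[:, 2] = np.log1p(clim[:, 2])
        return (clim - self.mean_) / self.sd_

    def scores(self, clim: np.ndarray) -> np.ndarray:
        """PCA scores (n, 2) of raw-unit climate rows."""
        return self.scale_climate(clim) @ self.components_.T

    def bin_of(self, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Half-open 100 x 100 binning of scores; the top edge is closed.

        Scores outside the bounds get index -1 on that axis.
        """
        scores = np.atleast_2d(scores)
        out = []
        for ax in range(2):
            lo, hi = self.bounds[ax]
            width = (hi - lo) / NBINS
            idx = np.floor((scores[:, ax] - lo) / width).astype(int)
            idx[scores[:, ax] == hi] = NBINS - 1  # closed top edge
            idx[(scores[:, ax] < lo) | (scores[:, ax] > hi)] = -1
            out.append(idx)
        return out[0], out[1]

    def bin_centres(self) -> tuple[np.ndarray, np.ndarray]:
        cx = self.bounds[0, 0] + (np.arange(NBINS) + 0.5) * (self.bounds[0, 1] - self.bounds[0, 0]) / NBINS
        cy = self.bounds[1, 0] + (np.arange(NBINS) + 0.5) * (self.bounds[1, 1] - self.bounds[1, 0]) / NBINS
        return cx, cy


def build_climate_space(grid: ClimateGrid, native_realm: int, introduced_realm: int) -> ClimateSpace:
    """Fit scaling + 2-axis PCA on the pooled realm climate and bin availability."""
    nat = grid.realm_climate(native_realm)
    intro = grid.realm_climate(introduced_realm)
    if len(nat) < 3 or len(intro) < 3:
        raise ValueError("need at least 3 land cells per realm")
    pooled = np.vstack([nat, intro]).astype(float)
    pooled[:, 2] = np.log1p(pooled[:, 2])
    mean = pooled.mean(axis=0)
    sd = pooled.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant climate variable; ordination degenerate")
    scaled = (pooled - mean) / sd

    pca = PCA(n_components=2)
    pca.fit(scaled)
    # bounds from the package's own projection so later score lookups are
    # bit-identical with the fitted ones
    scores = scaled @ pca.components_.T
    bounds = np.stack([scores.min(axis=0), scores.max(axis=0)], axis=1)

    space = ClimateSpace(
        mean_=mean, sd_=sd, components_=pca.components_,
        explained_variance_ratio_=pca.explained_variance_ratio_,
        bounds=bounds, native_realm=native_realm, introduced_realm=introduced_realm,
        avail_native=np.zeros((NBINS, NBINS)), avail_intro=np.zeros((NBINS, NBINS)),
    )
    for clim, target in ((nat, space.avail_native), (intro, space.avail_intro)):
        ix, iy = space.bin_of(space.scores(clim))
        np.add.at(target, (ix, iy), 1)
    return space


# -- kernel density ---------------------------------------------------------

@dataclass
class DensityGrid:
    """Raw, availability, and availability-corrected densities over PCA space."""

    raw: np.ndarray            # (100, 100) kernel occurrence density
    availability: np.ndarray   # kernel-smoothed availability density
    corrected: np.ndarray      # raw / availability, floored to 0
    bandwidth: float
    n_points: int

    @property
    def max_density(self) -> float:
        return float(self.corrected.max())


def _adhoc_bandwidth(scores: np.ndarray) -> float:
    """Ad hoc (reference) bivariate bandwidth: h = 0.5 (sd_x + sd_y) n^(-1/6)."""
    n = len(scores)
    sig = 0.5 * (scores[:, 0].std() + scores[:, 1].std())
    if sig == 0:
        sig = 1e-6
    return float(sig * n ** (-1.0 / 6.0))


def _kde_on_grid(scores: np.ndarray, weights: np.ndarray, h: float,
                 space: ClimateSpace) -> np.ndarray:
    cx, cy = space.bin_centres()
    kx = np.exp(-0.5 * ((cx[:, None] - scores[None, :, 0]) / h) ** 2)
    ky = np.exp(-0.5 * ((cy[:, None] - scores[None, :, 1]) / h) ** 2)
    dens = kx @ (weights[:, None] * ky.T)
    return dens / (2.0 * np.pi * h * h * weights.sum())


def occurrence_density(occs, space: ClimateSpace, grid: ClimateGrid,
                       realm: str = "native", min_points: int = 5) -> DensityGrid:
    """Availability-corrected kernel occurrence density in PCA climate space.

    ``occs`` is an :class:`OccurrenceSet` (records with the matching status are
    used) or an (n, 2) lon/lat array.  Occurrences in no-analogue climate
    (PCA cells not available in both realms) are removed first.  The KDE is
    evaluated over unique occurrence positions with multiplicity weights, so
    the corrected density is invariant to duplicating every record; the
    availability surface is smoothed with the same bandwidth.  Corrected
    densities below one thousandth of the maximum are zeroed.
    """
    if isinstance(occs, OccurrenceSet):
        status = "native" if realm == "native" else "naturalised"
        rec = occs.records[occs.records["status"] == status]
        pts = rec[["lon", "lat"]].to_numpy()
    else:
        pts = np.asarray(occs, dtype=float)
    clim = grid.climate_at(pts[:, 0], pts[:, 1])
    ok = np.isfinite(clim).all(axis=1)
    clim = clim[ok]
    scores = space.scores(clim)
    ix, iy = space.bin_of(scores)
    analogue = analogue_cells(space)
    inb = (ix >= 0) & (iy >= 0)
    keep = inb.copy()
    keep[inb] = analogue[ix[inb], iy[inb]]
    scores = scores[keep]
    if len(scores) == 0:
        raise ValueError("all occurrences fall in no-analogue climate")
    if len(scores) < min_points:
        raise ValueError(f"fewer than {min_points} occurrences after no-analogue removal")

    uniq, inv = np.unique(np.round(scores, 12), axis=0, return_inverse=True)
    weights = np.bincount(inv).astype(float)
    h = _adhoc_bandwidth(uniq)
    # the kernel cannot resolve below the discretisation of the climate space
    bin_w = (space.bounds[:, 1] - space.bounds[:, 0]).max() / NBINS
    h = max(h, bin_w)
    raw = _kde_on_grid(uniq, weights, h, space)

    avail_counts = space.avail_native if realm == "native" else space.avail_intro
    arows, acols = np.nonzero(avail_counts)
    cx, cy = space.bin_centres()
    avail_pts = np.column_stack([cx[arows], cy[acols]])
    avail = _kde_on_grid(avail_pts, avail_counts[arows, acols].astype(float), h, space)

    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = np.where(avail_counts > 0, raw / avail, 0.0)
    corrected[~np.isfinite(corrected)] = 0.0
    if corrected.max() > 0:
        corrected[corrected < DENSITY_FLOOR_RATIO * corrected.max()] = 0.0
    return DensityGrid(raw=raw, availability=avail, corrected=corrected,
                       bandwidth=h, n_points=int(weights.sum()))


def niche_cells(density: DensityGrid, core_quantile: float = 1.0) -> np.ndarray:
    """Boolean PCA-cell set of the native niche.

    ``core_quantile = 1.0`` keeps every cell with corrected density above zero;
    ``core_quantile = q`` keeps the smallest set of highest-density cells whose
    summed density reaches a fraction q of the total (the cell crossing the
    boundary is included; ties break on flattened cell index).
    """
    d = density.corrected
    if d.max() <= 0:
        raise ValueError("empty density grid")
    mask = d > 0
    if core_quantile >= 1.0:
        return mask
    flat = d.ravel()
    order = np.lexsort((np.arange(flat.size), -flat))  # density desc, index asc
    csum = np.cumsum(flat[order])
    target = core_quantile * flat.sum()
    k = int(np.searchsorted(csum, target - 1e-12)) + 1
    keep = np.zeros(flat.size, dtype=bool)
    keep[order[:k]] = flat[order[:k]] > 0
    return keep.reshape(d.shape)


def analogue_cells(space: ClimateSpace) -> np.ndarray:
    """PCA cells whose climate occurs in both the native and introduced realm."""
    return (space.avail_native > 0) & (space.avail_intro > 0)


# -- projection -------------------------------------------------------------

@dataclass
class PotentialRange:
    """Geographic cells of the naturalised realm with suitable climate."""

    rows: np.ndarray
    cols: np.ndarray
    area_km2: float
    realm: int
    core_quantile: float = 1.0
    analogue_masked: bool = True

    @property
    def n_cells(self) -> int:
        return self.rows.size

    def mask(self, grid: ClimateGrid) -> np.ndarray:
        m = np.zeros(grid.shape, dtype=bool)
        m[self.rows, self.cols] = True
        return m


def project_range(cells: np.ndarray, space: ClimateSpace, grid: ClimateGrid,
                  realm: int | None = None, core_quantile: float = 1.0) -> PotentialRange:
    """Map a PCA cell set back to the geographic cells of a realm.

    Every land cell of the realm whose climate falls in one of the PCA cells is
    included; area is the cos(latitude)-weighted sum of cell areas.
    """
    realm = space.introduced_realm if realm is None else realm
    rr, cc = grid.realm_cells(realm)
    clim = grid.climate[:, rr, cc].T
    ix, iy = space.bin_of(space.scores(clim))
    ok = (ix >= 0) & (iy >= 0)
    hit = ok.copy()
    hit[ok] = cells[ix[ok], iy[ok]]
    area = float(grid.cell_area_km2()[rr[hit], cc[hit]].sum())
    return PotentialRange(rows=rr[hit], cols=cc[hit], area_km2=area,
                          realm=realm, core_quantile=core_quantile)


def potential_range(occs, space: ClimateSpace, grid: ClimateGrid,
                    core_quantile: float = 1.0) -> PotentialRange:
    """Native density -> niche cells -> analogue masking -> projection."""
    dens = occurrence_density(occs, space, grid, realm="native")
    cells = niche_cells(dens, core_quantile) & analogue_cells(space)
    return project_range(cells, space, grid, space.introduced_realm, core_quantile)


# -- validation -------------------------------------------------------------

def tss(tp: float, fp: float, tn: float, fn: float) -> float:
    """True skill statistic: sensitivity + specificity - 1."""
    sens = tp / (tp + fn) if tp + fn > 0 else 0.0
    spec = tn / (tn + fp) if tn + fp > 0 else 0.0
    return sens + spec - 1.0


@dataclass
class CVReport:
    """Cross-validation scores: TSS per fold x pseudo-absence set, accuracy per fold."""

    tss: pd.DataFrame           # folds x pa_sets
    accuracy: np.ndarray        # per fold
    median_tss: float = field(init=False)
    sd_tss: float = field(init=False)
    median_accuracy: float = field(init=False)
    sd_accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        vals = self.tss.to_numpy().ravel()
        self.median_tss = float(np.median(vals))
        self.sd_tss = float(np.std(vals, ddof=1))
        self.median_accuracy = float(np.median(self.accuracy))
        self.sd_accuracy = float(np.std(self.accuracy, ddof=1))


def crossvalidate(occs: OccurrenceSet, grid: ClimateGrid, space: ClimateSpace,
                  folds: int = 5, pa_sets: int = 20, seed: int | None = 0,
                  core_quantile: float = 1.0) -> CVReport:
    """80/20 cross-validation of the native climate niche.

    The native data are split into ``folds`` disjoint validation sets; for each
    fold the niche is rebuilt on the training 80% and projected onto the native
    realm.  True-presence accuracy is the fraction of validation presences in
    suitable cells; TSS is scored against ``pa_sets`` pseudo-absence draws,
    each the size of the validation set, sampled from native-realm cells
    outside admin units with any native occurrence.
    """
    rng = np.random.default_rng(seed)
    native = occs.records[occs.records["status"] == "native"].reset_index(drop=True)
    n = len(native)
    if n < 5 * folds:
        raise ValueError("too few native occurrences for the requested folds")

    # pseudo-absence pool: realm cells in admin units free of native records
    row, col = grid.cell_of(native["lon"].to_numpy(), native["lat"].to_numpy())
    occupied_admins = set(grid.admin[row, col].tolist())
    rr, cc = grid.realm_cells(space.native_realm)
    free = ~np.isin(grid.admin[rr, cc], list(occupied_admins))
    pool = np.column_stack([rr[free], cc[free]])
    if len(pool) == 0:
        raise ValueError("no admin units free of native occurrences; no pseudo-absence pool")

    idx = rng.permutation(n)
    fold_idx = np.array_split(idx, folds)
    acc = np.zeros(folds)
    tss_mat = np.zeros((folds, pa_sets))
    for f, val in enumerate(fold_idx):
        train = native.drop(index=val)
        dens = occurrence_density(train[["lon", "lat"]].to_numpy(), space, grid,
                                  realm="native")
        cells = niche_cells(dens, core_quantile) & analogue_cells(space)
        suit = project_range(cells, space, grid, space.native_realm).mask(grid)

        vpts = native.loc[val]
        vrow, vcol = grid.cell_of(vpts["lon"].to_numpy(), vpts["lat"].to_numpy())
        pred_pres = suit[vrow, vcol]
        acc[f] = pred_pres.mean()
        tp, fn = int(pred_pres.sum()), int((~pred_pres).sum())
        for s in range(pa_sets):
            pick = rng.choice(len(pool), size=len(val), replace=len(pool) < len(val))
            pa = pool[pick]
            pa_suit = suit[pa[:, 0], pa[:, 1]]
            tss_mat[f, s] = tss(tp, int(pa_suit.sum()), int((~pa_suit).sum()), fn)
    return CVReport(tss=pd.DataFrame(tss_mat), accuracy=acc)
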