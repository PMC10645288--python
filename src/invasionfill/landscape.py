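"""Fragmentation metrics of binary suitability landscapes: contagion and clumpiness.

Both metrics are computed from cell-adjacency counts under the rook
(4-neighbour) rule with the interior double-count convention: every adjacent
pair of data cells contributes one count in each direction, and the landscape
border contributes nothing.  nodata cells are excluded from both the class
proportions and the adjacency sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BinaryLandscape", "adjacency_counts", "contagion", "clumpiness"]


@dataclass
class BinaryLandscape:
    """Adjacency summary of a classed raster.

    ``g[i, k]`` counts ordered adjacencies from class ``i`` to class ``k``
    (double-count: g is symmetric).  ``proportions[i]`` is the share of data
    cells in class ``i``; ``classes`` maps matrix index to class label.
    """

    classes: np.ndarray
    proportions: np.ndarray
    g: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.classes)


def _as_landscape(raster, nodata=None) -> BinaryLandscape:
    if isinstance(raster, BinaryLandscape):
        return raster
    return adjacency_counts(raster, nodata=nodata)


def adjacency_counts(raster: np.ndarray, nodata=None) -> BinaryLandscape:
    """Tally rook adjacencies and class proportions of a classed raster.

    Parameters
    ----------
    raster : 2-D array of class labels
    nodata : label to treat as missing (excluded everywhere), or None
    """
    r = np.asarray(raster)
    if r.ndim != 2:
        raise ValueError("raster must be 2-D")
    valid = np.ones(r.shape, dtype=bool) if nodata is None else (r != nodata)
    if not valid.any():
        raise ValueError("landscape contains no data cells")

    classes, inv = np.unique(r[valid], return_inverse=True)
    m = len(classes)
    idx = np.full(r.shape, -1, dtype=int)
    idx[valid] = inv
    counts = np.bincount(inv, minlength=m)
    proportions = counts / counts.sum()

    g = np.zeros((m, m), dtype=float)
    for a, b in (
        (idx[:, :-1], idx[:, 1:]),   # horizontal neighbours
        (idx[:-1, :], idx[1:, :]),   # vertical neighbours
    ):
        ok = (a >= 0) & (b >= 0)
        pair = a[ok] * m + b[ok]
        flat = np.bincount(pair, minlength=m * m).reshape(m, m)
        g += flat + flat.T  # count once from each side
    return BinaryLandscape(classes=classes, proportions=proportions, g=g)


def contagion(landscape, nodata=None) -> float:
    """Contagion index in [0, 100]: dominance and aggregation of the classes.

    ``100 * (1 + sum_ik q_ik ln q_ik / (2 ln m))`` with
    ``q_ik = P_i * g_ik / sum_k g_ik`` and ``0 ln 0 = 0``.  A single-class
    landscape (complete dominance) returns 100 by convention.
    """
    ls = _as_landscape(landscape, nodata)
    m = ls.n_classes
    if m == 1:
        return 100.0
    row_tot = ls.g.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        q = ls.proportions[:, None] * np.where(row_tot > 0, ls.g / np.where(row_tot == 0, 1, row_tot), 0.0)
        term = np.where(q > 0, q * np.log(q), 0.0)
    return float(100.0 * (1.0 + term.sum() / (2.0 * np.log(m))))


def clumpiness(landscape, focal_class=1, nodata=None) -> float:
    """Clumpiness index in [-1, 1] of the focal class: aggregation net of abundance.

    With ``G = g_ii / sum_k g_ik`` (proportion of the focal class's adjacencies
    that are like-adjacencies) and ``P`` the focal class proportion:
    ``(G - P) / P`` when ``G < P`` and ``P < 0.5``, else ``(G - P) / (1 - P)``.
    -1 is maximally disaggregated (checkerboard), 0 spatially random,
    1 maximally aggregated.
    """
    ls = _as_landscape(landscape, nodata)
    where = np.nonzero(ls.classes == focal_class)[0]
    if where.size == 0:
        raise ValueError(f"focal class {focal_class!r} absent from landscape")
    i = int(where[0])
    p = float(ls.proportions[i])
    if p >= 1.0:
        raise ValueError("clumpiness undefined for a single-class landscape (P = 1)")
    tot = ls.g[i].sum()
    gprop = float(ls.g[i, i] / tot) if tot > 0 else 0.0
    if gprop < p and p < 0.5:
        return (gprop - p) / p
    return (gprop - p) / (1.0 - p)
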