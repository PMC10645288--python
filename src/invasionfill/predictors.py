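"""Covariate construction for the range-filling regression.

Builds the model matrix linking each establishment event (one species in one
naturalised realm) to its introduction history, trait-based dispersal
estimate, habitat generalism, landscape fragmentation, and local recording
effort, with the transforms (logs, centring, scaling) applied before fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PredictorTable",
    "years_since_introduction",
    "local_recording_effort",
    "habitat_generalism",
    "estimate_dispersal",
    "standardize",
    "collinearity_report",
]


@dataclass
class PredictorTable:
    """Model-ready covariate table.

    ``data`` holds one row per establishment event.  ``response`` is the
    proportion response column (range filling); ``group`` the hierarchical
    grouping column (naturalised realm).  ``scaling`` maps each standardized
    continuous column to its (centre, scale) for back-transformation.
    """

    data: pd.DataFrame
    response: str = "filling"
    group: str = "realm"
    continuous: tuple[str, ...] = ()
    categorical: tuple[str, ...] = ()
    scaling: dict = field(default_factory=dict)

    def copy(self) -> "PredictorTable":
        return PredictorTable(self.data.copy(), self.response, self.group,
                              tuple(self.continuous), tuple(self.categorical),
                              dict(self.scaling))


def years_since_introduction(first_record_year, reference_year: int = 2017):
    """Time established: reference year minus the first confirmed record year."""
    year = np.asarray(first_record_year)
    if np.any(year > reference_year):
        raise ValueError("first record year is after the reference year")
    out = reference_year - year
    return out if out.ndim else int(out)


def local_recording_effort(potential, polygons, coverage: np.ndarray, grid) -> float:
    """Median sampling coverage over the unoccupied part of the potential range.

    Cells of the potential naturalised range covered by the occupied range
    polygons are excluded; returns NaN (with a warning) when no cell is
    unoccupied.
    """
    from .ranges import covered_mask  # local import to avoid a cycle

    unocc = potential.mask(grid) & ~covered_mask(polygons, grid)
    if not unocc.any():
        warnings.warn("potential range fully occupied; local effort undefined")
        return float("nan")
    return float(np.median(np.asarray(coverage)[unocc]))


def habitat_generalism(habitat_codes) -> float:
    """Habitat-breadth score: general classes as the integer part, sub-habitats
    as a two-digit decimal (``2.05`` = 2 general habitats, 5 sub-habitats).

    ``habitat_codes`` is a list of IUCN-style codes, e.g. ``["1", "1.1", "4.2"]``;
    codes with a dot are sub-habitats of the class before the dot.
    """
    codes = [str(c).strip() for c in habitat_codes if str(c).strip()]
    if not codes:
        warnings.warn("no habitat codes supplied; generalism recorded as 0 (missing)")
        return 0.0
    general = {c.split(".")[0] for c in codes}
    sub = {c for c in codes if "." in c}
    if len(sub) > 99:
        raise ValueError("more than 99 sub-habitats cannot be encoded")
    return len(general) + len(sub) / 100.0


def decode_generalism(score: float) -> tuple[int, int]:
    """Inverse of :func:`habitat_generalism`'s two-digit encoding."""
    general = int(np.floor(score + 1e-9))
    return general, int(round((score - general) * 100))


def estimate_dispersal(traits: dict, taxon: str, coef_config: dict) -> float:
    """Trait-based dispersal estimate.

    Plants: a ranked category 1-7 (increasing maximum dispersal distance on a
    roughly logarithmic scale).  Birds and mammals: natal dispersal distance in
    km from a linear form on the supplied traits (birds: diet, body mass,
    wingspan; mammals: body mass, home range size, trophic level).  The
    regression coefficients come from ``coef_config`` (user-supplied):
    ``{"intercept": a, "coefs": {trait: b, ...}, "log_traits": [...],
    "exp_response": bool}``.
    """
    intercept = float(coef_config.get("intercept", 0.0))
    coefs = coef_config.get("coefs", {})
    logged = set(coef_config.get("log_traits", ()))
    value = intercept
    for name, beta in coefs.items():
        if name not in traits or traits[name] is None or (
                isinstance(traits[name], float) and np.isnan(traits[name])):
            raise ValueError(f"missing required trait {name!r} for taxon {taxon!r}")
        x = float(traits[name])
        if name in logged:
            if x <= 0:
                raise ValueError(f"trait {name!r} must be positive to log")
            x = np.log(x)
        value += beta * x
    if coef_config.get("exp_response", False):
        value = float(np.exp(value))
    if taxon == "plant":
        rank = int(round(value))
        if not 1 <= rank <= 7:
            raise ValueError(f"plant dispersal rank {rank} outside 1-7")
        return float(rank)
    if value < 0:
        raise ValueError("negative dispersal distance from config")
    return float(value)


def standardize(table: PredictorTable, log_columns: tuple[str, ...] = (),
                sd_scale: float = 1.0) -> PredictorTable:
    """Log the stated columns, then centre and scale every continuous column.

    Centring is on the mean; scaling divides by ``sd_scale`` sample standard
    deviations (ddof=1).  Scaling metadata is stored so the operation is
    idempotent and invertible; already-standardized columns are left alone.
    """
    out = table.copy()
    df = out.data
    for col in log_columns:
        key = f"log:{col}"
        if key in out.scaling:
            continue
        if (df[col] <= 0).any():
            raise ValueError(f"column {col!r} must be positive before log")
        df[col] = np.log(df[col])
        out.scaling[key] = True
    for col in out.continuous:
        if col in out.scaling:
            continue
        if df[col].isna().any():
            raise ValueError(f"missing values in fitted column {col!r}")
        centre = float(df[col].mean())
        scale = float(df[col].std(ddof=1)) * sd_scale
        if scale == 0:
            raise ValueError(f"column {col!r} is constant; cannot scale")
        df[col] = (df[col] - centre) / scale
        out.scaling[col] = (centre, scale)
    return out


def back_transform(table: PredictorTable, column: str) -> np.ndarray:
    """Undo centring/scaling (not the log) of a standardized column."""
    centre, scale = table.scaling[column]
    return table.data[column].to_numpy() * scale + centre


def collinearity_report(table: PredictorTable, r2_threshold: float = 0.5) -> pd.DataFrame:
    """Pairwise correlations among continuous covariates, flagging collinear pairs.

    Pairs with squared Pearson correlation above the threshold should not enter
    the same multivariate model; they are resolved by fitting alternative models.
    """
    cols = list(table.continuous)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = float(table.data[a].corr(table.data[b]))
            rows.append({"var_a": a, "var_b": b, "r": r, "r2": r * r,
                         "flagged": r * r > r2_threshold})
    return pd.DataFrame(rows, columns=["var_a", "var_b", "r", "r2", "flagged"])
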