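"""Canned recovery experiments: the package's self-calibration studies.

These functions wire the synthetic world to the estimation pipeline under
fixed study conditions and report how well known ground truth is recovered:

* :func:`niche_recovery_experiment` — species with known bivariate Gaussian
  niches and a known filling fraction; measures the Jaccard overlap of the
  projected potential range with the true suitable area and the error of the
  range-filling estimate.
* :func:`cv_experiment` — cross-validation scores for well-sampled species.
* :func:`coefficient_recovery` — simulate establishment events from a
  reference coefficient set with the hierarchical beta-logit model and refit.
* :func:`null_calibration` — repeated fits on data generated with all
  coefficients zero; counts fits flagging any covariate significant.

Study conditions (world size, niche breadth, occurrence counts) are fixed
here so results are comparable across runs; see the methods notes for the
rationale behind each choice.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import demo
from .betareg import MCMCSettings, ModelSpec, fit, significance
from .niche import build_climate_space, crossvalidate, potential_range
from .ranges import range_filling, range_polygons
from .synthetic_world import (SpeciesTruth, WorldConfig, make_regression_data,
                              make_species, make_world, true_suitable_mask)

#: world used for the niche-recovery studies: large enough that the 100 x 100
#: climate space is densely available, short climate correlation lengths so
#: realms sample many independent climates
RECOVERY_WORLD = dict(nrows=200, ncols=200, corr_length=(3.0, 2.0, 3.0))
#: niche breadth as a fraction of the realm climate sd; broad-ranging species
NICHE_SD_FRACTION = 0.7
#: niche centres drawn from the middle of the realm climate distribution
CENTRE_QUANTILES = (0.4, 0.6)
N_NATIVE_OCCURRENCES = 200


def _species_truths(grid, n_species: int, f_true: float, rng) -> list[SpeciesTruth]:
    clim = grid.realm_climate(1)[:, [0, 2]]
    sd = clim.std(axis=0) * NICHE_SD_FRACTION
    out = []
    for k in range(n_species):
        q = rng.uniform(*CENTRE_QUANTILES, 2)
        centre = np.array([np.quantile(clim[:, 0], q[0]),
                           np.quantile(clim[:, 1], q[1])])
        out.append(SpeciesTruth(f"species_{k + 1}", centre, np.diag(sd ** 2),
                                native_realm=1, introduced_realm=2, f_true=f_true))
    return out


def niche_recovery_experiment(n_species: int = 200, f_true: float = 0.5,
                              seed: int = 0) -> pd.DataFrame:
    """Per-species Jaccard overlap with truth and range-filling estimates.

    Each species gets 200 native occurrences; the potential naturalised range
    is estimated with default KDE settings and compared with the true suitable
    area (same one-thousandth density convention); range filling is estimated
    from the admin-unit convex hulls of its naturalised occurrences.
    """
    rng = np.random.default_rng(seed)
    grid = make_world(WorldConfig(**RECOVERY_WORLD, seed=seed))
    space = build_climate_space(grid, 1, 2)
    rows = []
    for truth in _species_truths(grid, n_species, f_true, rng):
        occ = make_species(grid, truth, n_native=N_NATIVE_OCCURRENCES, rng=rng)
        if occ.too_few_suitable:
            continue
        pot = potential_range(occ, space, grid)
        tm = true_suitable_mask(grid, truth)
        est = pot.mask(grid)
        jac = (est & tm).sum() / (est | tm).sum()
        fill = range_filling(pot, range_polygons(occ, grid, 2), grid)
        rows.append({"species": truth.species, "f_true": truth.f_true,
                     "jaccard": float(jac), "filling": float(fill)})
    return pd.DataFrame(rows)


def cv_experiment(n_species: int = 5, seed: int = 0) -> pd.DataFrame:
    """Cross-validate well-sampled synthetic species (5 folds x 20 PA sets)."""
    rng = np.random.default_rng(seed)
    grid = make_world(WorldConfig(**RECOVERY_WORLD, seed=seed))
    space = build_climate_space(grid, 1, 2)
    rows = []
    for k, truth in enumerate(_species_truths(grid, n_species, 0.5, rng)):
        occ = make_species(grid, truth, n_native=N_NATIVE_OCCURRENCES, rng=rng)
        rep = crossvalidate(occ, grid, space, seed=seed + k)
        rows.append({"species": truth.species,
                     "median_accuracy": rep.median_accuracy,
                     "median_tss": rep.median_tss})
    return pd.DataFrame(rows)


def coefficient_recovery(taxon: str, seed: int = 0,
                         mcmc: MCMCSettings | None = None) -> pd.DataFrame:
    """Simulate events from a reference taxon model at n = 5000 and refit.

    Returns one row per slope with the generating value, the posterior mean,
    and their difference.
    """
    model = demo.TAXON_MODELS[taxon]
    table = make_regression_data(
        model["coefs"], realm_sd=demo.RECOVERY_REALM_SD, phi=demo.RECOVERY_PHI,
        n=demo.RECOVERY_N, n_realms=demo.RECOVERY_N_REALMS, seed=seed,
        intercept=model["intercept"])
    spec = ModelSpec(continuous=tuple(model["coefs"]), group="realm")
    post = fit(table, spec, mcmc=mcmc, seed=seed)
    rows = [{"parameter": name, "true": true, "posterior_mean": post.mean(name),
             "error": post.mean(name) - true, "converged": post.converged}
            for name, true in model["coefs"].items()]
    return pd.DataFrame(rows)


def null_calibration(n_replicates: int = 20, n: int = 2000, n_covariates: int = 1,
                     seed: int = 0, mcmc: MCMCSettings | None = None) -> pd.DataFrame:
    """Fits on all-zero-coefficient data: false-positive rate of the
    mean / 2.5th / 97.5th percentile significance rule.

    Returns one row per replicate with whether any covariate was flagged.
    """
    coefs = {f"x{j + 1}": 0.0 for j in range(n_covariates)}
    mcmc = mcmc or MCMCSettings()
    rows = []
    for r in range(n_replicates):
        table = make_regression_data(coefs, realm_sd=0.3, phi=demo.RECOVERY_PHI,
                                     n=n, n_realms=6, seed=seed + 1000 + r)
        spec = ModelSpec(continuous=tuple(coefs), group="realm")
        post = fit(table, spec, mcmc=mcmc, seed=seed + r)
        sig = significance(post)
        flagged = bool(sig.loc[sig["parameter"] != "intercept", "significant"].any())
        rows.append({"replicate": r, "any_significant": flagged,
                     "converged": post.converged})
    return pd.DataFrame(rows)
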