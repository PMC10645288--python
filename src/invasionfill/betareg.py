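"""Hierarchical Bayesian beta regression for range filling.

The response (range filling, a proportion) is modelled
``y ~ Beta(mu * phi, (1 - mu) * phi)`` with
``logit(mu) = b0 + sum_k b_k x_k + u_realm + sum_k v_{k,realm} x_k``:
global intercept and slopes, realm-level intercept offsets, and optional
realm-varying slopes.  Priors are weakly informative and centred on the null:
Normal(0, 2.5) on fixed effects, half-Cauchy(2.5) on the group standard
deviations, half-Cauchy(5) on the precision phi.  Categorical covariates are
handled like the realm term: per-level offsets sharing a half-Cauchy sd.

Sampling uses an affine-invariant ensemble sampler over the joint posterior
density defined here (group sds and phi sampled on the log scale with the
Jacobian included).  Walkers serve as chains for the potential-scale-reduction
convergence check; sampling is extended when the check fails.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit

from .predictors import PredictorTable

__all__ = [
    "PriorConfig", "ModelSpec", "MCMCSettings", "Posterior", "FitReport",
    "fit", "diagnostics", "significance", "select_model", "filling_vs_cells",
    "screen_univariate", "prior_predictive",
]


@dataclass(frozen=True)
class PriorConfig:
    beta_scale: float = 2.5   # Normal sd on intercept and slopes
    sd_scale: float = 2.5     # half-Cauchy scale on group sds
    phi_scale: float = 5.0    # half-Cauchy scale on the precision


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: covariates, hierarchy, priors."""

    response: str = "filling"
    continuous: tuple[str, ...] = ()
    categorical: tuple[str, ...] = ()
    group: str = "realm"
    varying_slopes: tuple[str, ...] = ()
    priors: PriorConfig = field(default_factory=PriorConfig)


@dataclass(frozen=True)
class MCMCSettings:
    """Chain settings; draw counts are totals pooled across walkers."""

    n_burn: int = 10_000
    n_draws: int = 20_000
    n_walkers: int = 40
    max_extensions: int = 3
    rhat_threshold: float = 1.05


# -- internal design --------------------------------------------------------

@dataclass
class _Design:
    y: np.ndarray
    logit_y: np.ndarray
    X: np.ndarray                 # (n, k) continuous covariates
    cov_names: tuple[str, ...]
    groups: dict                  # term name -> (index array, level labels)
    varying: tuple[str, ...]      # covariate names with realm-varying slopes
    group_term: str
    priors: PriorConfig
    names: list                   # flat parameter names, one per theta entry
    slices: dict                  # term -> slice into theta

    @property
    def ndim(self) -> int:
        return len(self.names)


def _compress_boundaries(y: np.ndarray) -> np.ndarray:
    """Shrink exact 0/1 responses into the open interval: (y(n-1) + 0.5)/n."""
    y = np.asarray(y, dtype=float)
    if np.any((y <= 0.0) | (y >= 1.0)):
        n = y.size
        y = (y * (n - 1) + 0.5) / n
    return y


def _build_design(table: PredictorTable, spec: ModelSpec) -> _Design:
    df = table.data
    for c in spec.continuous + spec.categorical + (spec.group,):
        if c not in df.columns:
            raise ValueError(f"covariate {c!r} missing from table")
    y = _compress_boundaries(df[spec.response].to_numpy())
    if np.any((y <= 0.0) | (y >= 1.0)):
        raise ValueError("response outside (0,1) after boundary compression")
    X = df[list(spec.continuous)].to_numpy(dtype=float) if spec.continuous else np.zeros((len(df), 0))

    groups = {}
    for term in (spec.group,) + spec.categorical:
        levels, idx = np.unique(df[term].astype(str).to_numpy(), return_inverse=True)
        if term == spec.group and len(levels) < 2:
            raise ValueError("hierarchical grouping needs at least 2 levels")
        groups[term] = (idx, tuple(levels))

    names: list[str] = ["intercept"]
    slices: dict[str, slice] = {"intercept": slice(0, 1)}

    def add(term_names, key):
        start = len(names)
        names.extend(term_names)
        slices[key] = slice(start, len(names))

    add(list(spec.continuous), "beta")
    for term, (_, levels) in groups.items():
        add([f"u_{term}[{lv}]" for lv in levels], f"u:{term}")
        add([f"sigma_{term}"], f"logsigma:{term}")
    for cov in spec.varying_slopes:
        if cov not in spec.continuous:
            raise ValueError(f"varying slope for unknown covariate {cov!r}")
        levels = groups[spec.group][1]
        add([f"v_{cov}[{lv}]" for lv in levels], f"v:{cov}")
        add([f"sigma_{cov}"], f"logsigma_v:{cov}")
    add(["phi"], "logphi")

    return _Design(y=y, logit_y=logit(y), X=X, cov_names=spec.continuous,
                   groups=groups, varying=tuple(spec.varying_slopes),
                   group_term=spec.group, priors=spec.priors,
                   names=names, slices=slices)


def _linear_predictor(theta: np.ndarray, d: _Design) -> np.ndarray:
    """eta (W, n) for a (W, ndim) batch of parameter vectors."""
    theta = np.atleast_2d(theta)
    eta = theta[:, d.slices["intercept"]]  # (W, 1)
    eta = np.repeat(eta, d.y.size, axis=1)
    if d.X.shape[1]:
        eta += theta[:, d.slices["beta"]] @ d.X.T
    for term, (gidx, _) in d.groups.items():
        eta += theta[:, d.slices[f"u:{term}"]][:, gidx]
    gidx = d.groups[d.group_term][0]
    for cov in d.varying:
        j = d.cov_names.index(cov)
        eta += theta[:, d.slices[f"v:{cov}"]][:, gidx] * d.X[None, :, j]
    return eta


def _log_likelihood(theta: np.ndarray, d: _Design) -> np.ndarray:
    """Pointwise beta log-likelihood, (W, n)."""
    theta = np.atleast_2d(theta)
    eta = _linear_predictor(theta, d)
    mu = np.clip(expit(eta), 1e-10, 1.0 - 1e-10)
    phi = np.exp(theta[:, d.slices["logphi"]])  # (W, 1)
    a = mu * phi
    b = (1.0 - mu) * phi
    lny = np.log(d.y)
    ln1y = np.log1p(-d.y)
    return ((a - 1.0) * lny + (b - 1.0) * ln1y
            + gammaln(phi) - gammaln(a) - gammaln(b))


def _half_cauchy_logpdf(x: np.ndarray, scale: float) -> np.ndarray:
    return np.log(2.0 / (np.pi * scale)) - np.log1p((x / scale) ** 2)


def _log_posterior(theta: np.ndarray, d: _Design) -> np.ndarray:
    theta = np.atleast_2d(theta)
    lp = _log_likelihood(theta, d).sum(axis=1)
    pr = d.priors

    fixed = np.concatenate([theta[:, d.slices["intercept"]],
                            theta[:, d.slices["beta"]]], axis=1)
    lp += -0.5 * (fixed / pr.beta_scale) ** 2 @ np.ones(fixed.shape[1])

    def hier(offset_key, sigma_key):
        u = theta[:, d.slices[offset_key]]
        logsig = theta[:, d.slices[sigma_key]][:, 0]
        sig = np.exp(logsig)
        out = -0.5 * (u / sig[:, None]) ** 2 @ np.ones(u.shape[1])
        out += -u.shape[1] * logsig
        out += _half_cauchy_logpdf(sig, pr.sd_scale) + logsig  # prior + Jacobian
        return out

    for term in d.groups:
        lp += hier(f"u:{term}", f"logsigma:{term}")
    for cov in d.varying:
        lp += hier(f"v:{cov}", f"logsigma_v:{cov}")

    logphi = theta[:, d.slices["logphi"]][:, 0]
    lp += _half_cauchy_logpdf(np.exp(logphi), pr.phi_scale) + logphi
    return np.where(np.isfinite(lp), lp, -np.inf)


# -- posterior container ----------------------------------------------------

@dataclass
class Posterior:
    """MCMC draws with chain metadata and convergence diagnostics.

    ``chain`` has shape (n_walkers, n_steps, ndim); walkers act as chains for
    the potential-scale-reduction statistic.
    """

    chain: np.ndarray
    names: list
    spec: ModelSpec
    settings: MCMCSettings
    rhat_max: float
    converged: bool
    n_extensions: int
    _design: _Design = field(repr=False, default=None)

    def _col(self, name: str) -> int:
        return self.names.index(name)

    def draws(self, name: str) -> np.ndarray:
        """Pooled draws of one parameter (sds and phi returned on natural scale)."""
        vals = self.chain[:, :, self._col(name)].ravel()
        if name == "phi" or name.startswith("sigma_"):
            vals = np.exp(vals)
        return vals

    def mean(self, name: str) -> float:
        return float(self.draws(name).mean())

    def quantiles(self, name: str, qs=(0.025, 0.975)) -> np.ndarray:
        return np.quantile(self.draws(name), qs)

    @property
    def n_draws(self) -> int:
        return self.chain.shape[0] * self.chain.shape[1]

    def realm_levels(self) -> tuple[str, ...]:
        return self._design.groups[self._design.group_term][1]

    def realm_effect_draws(self, covariate: str | None = None) -> dict:
        """Per-realm draws of intercept (b0 + u_r) or slope (b_k + v_{k,r})."""
        levels = self.realm_levels()
        out = {}
        for lv in levels:
            if covariate is None:
                vals = (self.draws("intercept")
                        + self.draws(f"u_{self._design.group_term}[{lv}]"))
            else:
                vals = self.draws(covariate)
                if covariate in self._design.varying:
                    vals = vals + self.draws(f"v_{covariate}[{lv}]")
            out[lv] = vals
        return out

    def to_arviz(self, thin_loglik: int | None = 500) -> az.InferenceData:
        """InferenceData with (optionally thinned) pointwise log-likelihood."""
        post = {n: self.chain[:, :, i] for i, n in enumerate(self.names)}
        groups = {"posterior": post}
        if thin_loglik and self._design is not None:
            nw, ns, _ = self.chain.shape
            step = max(1, (nw * ns) // thin_loglik)
            flat = self.chain.reshape(-1, self.chain.shape[2])[::step]
            ll = _log_likelihood(flat, self._design)
            groups["log_likelihood"] = {"y": ll[None, :, :]}
        return az.from_dict(**groups)


def _initial_state(d: _Design, n_walkers: int, rng: np.random.Generator) -> np.ndarray:
    """Start walkers in a ball around a crude moment-based estimate."""
    z = d.logit_y
    beta0 = float(np.mean(z))
    init = np.zeros(d.ndim)
    init[d.slices["intercept"]] = beta0
    if d.X.shape[1]:
        coef, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(d.y.size), d.X]), z, rcond=None)
        init[d.slices["intercept"]] = coef[0]
        init[d.slices["beta"]] = coef[1:]
    for term in d.groups:
        init[d.slices[f"logsigma:{term}"]] = np.log(0.3)
    for cov in d.varying:
        init[d.slices[f"logsigma_v:{cov}"]] = np.log(0.3)
    mu = np.clip(expit(init[d.slices["intercept"]][0]), 0.05, 0.95)
    resid_var = max(np.var(d.y), 1e-4)
    init[d.slices["logphi"]] = np.log(max(mu * (1 - mu) / resid_var - 1.0, 2.0))
    ball = init + 0.05 * rng.standard_normal((n_walkers, d.ndim))
    return ball


def _rhat_max(chain: np.ndarray) -> float:
    ds = az.convert_to_dataset({"theta": chain})
    r = az.rhat(ds)["theta"].values
    return float(np.nanmax(r))


def fit(table: PredictorTable, spec: ModelSpec,
        mcmc: MCMCSettings | None = None, seed: int = 0) -> Posterior:
    """Sample the posterior of the hierarchical beta-logit model.

    Burn-in and sampling lengths are pooled draw counts split across the
    walker ensemble.  Convergence requires potential scale reduction below
    the threshold on every parameter; otherwise sampling is extended (up to
    ``max_extensions`` times) and the fit is flagged unconverged if the check
    still fails.  Same seed, same data: identical draws.
    """
    mcmc = mcmc or MCMCSettings()
    d = _build_design(table, spec)
    n_walkers = max(mcmc.n_walkers, 2 * d.ndim + 2)
    n_walkers += n_walkers % 2
    burn_steps = max(1, int(np.ceil(mcmc.n_burn / n_walkers)))
    samp_steps = max(2, int(np.ceil(mcmc.n_draws / n_walkers)))

    rng = np.random.default_rng(seed)
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(n_walkers, d.ndim, _log_posterior,
                                    args=(d,), vectorize=True, moves=moves)
    sampler.random_state = np.random.RandomState(
        int(np.random.SeedSequence(seed).generate_state(1)[0])).get_state()
    state = _initial_state(d, n_walkers, rng)
    state = sampler.run_mcmc(state, burn_steps)
    sampler.reset()
    extensions = 0
    while True:
        state = sampler.run_mcmc(state, samp_steps)
        chain = np.swapaxes(sampler.get_chain(), 0, 1)  # (walkers, steps, dim)
        rhat = _rhat_max(chain)
        if rhat < mcmc.rhat_threshold or extensions >= mcmc.max_extensions:
            break
        extensions += 1
    return Posterior(chain=chain, names=list(d.names), spec=spec, settings=mcmc,
                     rhat_max=rhat, converged=bool(rhat < mcmc.rhat_threshold),
                     n_extensions=extensions, _design=d)


# -- diagnostics ------------------------------------------------------------

@dataclass
class FitReport:
    dic: float
    p_d: float
    waic: float
    loo: float
    pseudo_r2: float
    pearson_resid_sd: float
    converged: bool


def diagnostics(post: Posterior, thin: int = 500) -> FitReport:
    """DIC (with effective parameters), WAIC, LOO, pseudo-R2, Pearson residuals.

    Pseudo-R2 is the squared sample correlation between the posterior-mean
    linear predictor and the logit of the response.
    """
    d = post._design
    nw, ns, ndim = post.chain.shape
    flat = post.chain.reshape(-1, ndim)
    step = max(1, flat.shape[0] // thin)
    sub = flat[::step]

    ll = _log_likelihood(sub, d)          # (draws, n)
    dev = -2.0 * ll.sum(axis=1)
    theta_bar = flat.mean(axis=0)
    dev_at_mean = float(-2.0 * _log_likelihood(theta_bar, d).sum())
    p_d = float(dev.mean() - dev_at_mean)
    dic = float(dev.mean() + p_d)

    idata = az.from_dict(posterior={"theta": sub[None, :, :]},
                         log_likelihood={"y": ll[None, :, :]})
    with np.errstate(over="ignore", invalid="ignore"):
        waic = float(az.waic(idata, scale="deviance").elpd_waic)
        loo = float(az.loo(idata, scale="deviance").elpd_loo)

    eta_bar = _linear_predictor(sub, d).mean(axis=0)
    pseudo_r2 = float(np.corrcoef(eta_bar, d.logit_y)[0, 1] ** 2)

    mu_bar = expit(eta_bar)
    phi_bar = float(np.exp(sub[:, d.slices["logphi"]]).mean())
    resid = (d.y - mu_bar) / np.sqrt(mu_bar * (1 - mu_bar) / (1 + phi_bar))
    return FitReport(dic=dic, p_d=p_d, waic=waic, loo=loo, pseudo_r2=pseudo_r2,
                     pearson_resid_sd=float(resid.std(ddof=1)),
                     converged=post.converged)


def significance(post: Posterior, level: float = 0.95,
                 realm_level: float = 0.90) -> pd.DataFrame:
    """Significance calls for the global fixed effects and realm differences.

    A parameter is significant when its posterior mean and both tail quantiles
    (at ``level``) share a sign.  A covariate shows realm differences when the
    ``realm_level`` intervals of two realms' effects are disjoint.
    """
    lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
    rows = []
    for name in ("intercept",) + post.spec.continuous:
        draws = post.draws(name)
        m, q_lo, q_hi = draws.mean(), *np.quantile(draws, [lo, hi])
        sig = (m > 0 and q_lo > 0 and q_hi > 0) or (m < 0 and q_lo < 0 and q_hi < 0)

        realm_diff = False
        if post._design is not None and (
                name == "intercept" or name in post.spec.varying_slopes):
            eff = post.realm_effect_draws(None if name == "intercept" else name)
            r_lo, r_hi = (1 - realm_level) / 2, 1 - (1 - realm_level) / 2
            ivs = [np.quantile(v, [r_lo, r_hi]) for v in eff.values()]
            for i in range(len(ivs)):
                for j in range(i + 1, len(ivs)):
                    if ivs[i][1] < ivs[j][0] or ivs[j][1] < ivs[i][0]:
                        realm_diff = True
        rows.append({"parameter": name, "mean": float(m), "q_lo": float(q_lo),
                     "q_hi": float(q_hi), "significant": bool(sig),
                     "realm_difference": bool(realm_diff)})
    return pd.DataFrame(rows)


# -- model selection --------------------------------------------------------

def screen_univariate(table: PredictorTable, covariates=None,
                      mcmc: MCMCSettings | None = None, seed: int = 0,
                      level: float = 0.90) -> pd.DataFrame:
    """Stage-1 screening: one model per covariate, realm as hierarchical effect.

    A covariate passes when its 90% interval excludes zero globally, or when
    its realm-varying slopes differ between two realms (disjoint 90% intervals).
    """
    covariates = tuple(covariates or table.continuous)
    rows = []
    for i, cov in enumerate(covariates):
        spec = ModelSpec(response=table.response, continuous=(cov,),
                         group=table.group, varying_slopes=(cov,))
        post = fit(table, spec, mcmc=mcmc, seed=seed + i)
        sig = significance(post, level=level, realm_level=level)
        row = sig[sig["parameter"] == cov].iloc[0].to_dict()
        row["covariate"] = cov
        row["keep"] = bool(row["significant"] or row["realm_difference"])
        row["converged"] = post.converged
        rows.append(row)
    return pd.DataFrame(rows)


def select_model(table: PredictorTable, candidates=None,
                 mcmc: MCMCSettings | None = None, seed: int = 0,
                 r2_threshold: float = 0.5, delta_dic: float = 5.0):
    """Staged model selection mirroring the screening / parsimony procedure.

    1. univariate screening keeps covariates with a global or realm-specific
       90% effect; 2. collinear pairs (squared correlation above threshold)
       spawn alternative candidate models; 3. a candidate that fails to
       converge drops its covariate with mean estimate nearest zero and is
       refitted; 4. candidates within ``delta_dic`` of the best DIC are all
       plausible and the most parsimonious is selected.

    Returns (selected ModelSpec, report DataFrame over all candidates).
    """
    from .predictors import collinearity_report

    if candidates is None:
        screen = screen_univariate(table, mcmc=mcmc, seed=seed)
        kept = tuple(screen.loc[screen["keep"], "covariate"])
        cand_sets = [kept]
        flagged = collinearity_report(
            replace_continuous(table, kept), r2_threshold)
        for _, pair in flagged[flagged["flagged"]].iterrows():
            for drop in (pair["var_a"], pair["var_b"]):
                alt = tuple(c for c in kept if c != drop)
                if alt not in cand_sets:
                    cand_sets.append(alt)
        if () not in cand_sets:
            cand_sets.append(())  # intercept-only fallback
        candidates = [ModelSpec(response=table.response, continuous=cs,
                                group=table.group) for cs in cand_sets]

    rows = []
    fits = []
    for i, spec in enumerate(candidates):
        current = spec
        post = fit(table, current, mcmc=mcmc, seed=seed + 100 + i)
        while not post.converged and current.continuous:
            means = {c: abs(post.mean(c)) for c in current.continuous}
            drop = min(means, key=means.get)
            current = replace(current, continuous=tuple(
                c for c in current.continuous if c != drop))
            post = fit(table, current, mcmc=mcmc, seed=seed + 100 + i)
        rep = diagnostics(post)
        fits.append((current, post, rep))
        rows.append({"candidate": i, "covariates": ",".join(current.continuous),
                     "n_covariates": len(current.continuous),
                     "dic": rep.dic, "waic": rep.waic,
                     "converged": post.converged})
    report = pd.DataFrame(rows)
    ok = report[report["converged"]]
    if ok.empty:
        raise RuntimeError("no candidate model converged")
    best = float(ok["dic"].min())
    report["plausible"] = report["converged"] & (report["dic"] <= best + delta_dic)
    plaus = report[report["plausible"]].sort_values(["n_covariates", "dic"])
    chosen = int(plaus.iloc[0]["candidate"])
    report["selected"] = report["candidate"] == chosen
    return fits[chosen][0], report


def replace_continuous(table: PredictorTable, cols) -> PredictorTable:
    out = table.copy()
    out.continuous = tuple(cols)
    return out


def filling_vs_cells(records: pd.DataFrame, mcmc: MCMCSettings | None = None,
                     seed: int = 0, filling_col: str = "filling",
                     cells_col: str = "n_cells", group: str = "realm") -> Posterior:
    """Sensitivity model: range filling vs log occupied-cell count.

    Same beta-logit machinery with log(cell count), standardized, as the sole
    continuous covariate and realm as the hierarchical effect.
    """
    df = records.copy()
    x = np.log(df[cells_col].to_numpy(dtype=float))
    df["log_cells"] = (x - x.mean()) / x.std(ddof=1)
    table = PredictorTable(data=df, response=filling_col, group=group,
                           continuous=("log_cells",))
    spec = ModelSpec(response=filling_col, continuous=("log_cells",), group=group)
    return fit(table, spec, mcmc=mcmc, seed=seed)


def prior_predictive(table: PredictorTable, spec: ModelSpec, n_draws: int = 200,
                     seed: int = 0) -> np.ndarray:
    """Draw responses from the prior predictive; all values lie in (0, 1)."""
    d = _build_design(table, spec)
    rng = np.random.default_rng(seed)
    pr = spec.priors
    out = np.empty((n_draws, d.y.size))
    for i in range(n_draws):
        theta = np.zeros(d.ndim)
        theta[d.slices["intercept"]] = rng.normal(0, pr.beta_scale)
        theta[d.slices["beta"]] = rng.normal(0, pr.beta_scale, d.X.shape[1])
        for term, (_, levels) in d.groups.items():
            sig = abs(rng.standard_cauchy()) * pr.sd_scale
            theta[d.slices[f"u:{term}"]] = rng.normal(0, sig, len(levels))
            theta[d.slices[f"logsigma:{term}"]] = np.log(sig)
        for cov in d.varying:
            sig = abs(rng.standard_cauchy()) * pr.sd_scale
            theta[d.slices[f"v:{cov}"]] = rng.normal(
                0, sig, len(d.groups[d.group_term][1]))
            theta[d.slices[f"logsigma_v:{cov}"]] = np.log(sig)
        phi = abs(rng.standard_cauchy()) * pr.phi_scale + 1e-3
        theta[d.slices["logphi"]] = np.log(phi)
        mu = np.clip(expit(_linear_predictor(theta, d)[0]), 1e-9, 1 - 1e-9)
        out[i] = np.clip(rng.beta(mu * phi, (1 - mu) * phi), 1e-12, 1 - 1e-12)
    return out
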