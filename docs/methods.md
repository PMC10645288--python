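# Methods

`invasionfill` quantifies the *invasion deficit* of naturalised species: the
gap between the area a species' naturalised range currently occupies and the
area that is climatically suitable for it in the realm it was introduced to.
This note describes the models and procedures the package implements, the
parameters that matter, what the synthetic world does and does not emulate,
and the numerical choices made where the design was open.

## Climate-matching niche model

**Climate space.** For each native/naturalised realm pair, the climate of
every 10 arc-minute land cell in both realms (mean temperature of the coldest
month, mean temperature of the warmest month, total annual precipitation) is
pooled; precipitation is log-transformed (`log1p`, so zero-precipitation
cells are tolerated), all variables are scaled to mean 0 / sd 1 over the
pooled cells, and a principal-components analysis reduces them to two axes.
The score range of the pooled cells defines a 100 × 100 discretisation with
half-open bins (top edge closed) so every cell maps to exactly one bin.
Bin bounds are computed from the package's own projection arithmetic so that
later lookups of the same climate are bit-identical.

**Occurrence density.** Native occurrence records are mapped into the climate
space and smoothed with a bivariate normal kernel.  The bandwidth uses the
ad hoc (reference) rule from kernel home-range estimation,
`h = 0.5 (sd_x + sd_y) n^(-1/6)`, shared by both axes.  Two numerical
choices:

* the kernel is evaluated over *unique* occurrence positions with
  multiplicity weights, and `n` in the bandwidth is the number of unique
  positions — this makes the density invariant to duplicated records;
* the bandwidth is floored at one climate-space bin width, since the kernel
  cannot meaningfully resolve below the discretisation.

**Availability correction.** The occurrence density is divided bin-wise by a
kernel-smoothed availability density (the realm's cells in climate space,
same bandwidth), and set to zero wherever the realm has no cells at all.
This corrects for the fact that occurrences concentrate in climates that are
common in the realm, not only in climates the species prefers.  Bins whose
corrected density falls below one thousandth of the maximum corrected
density are set to zero; this threshold removes the infinitesimal kernel
tails.  The threshold is applied after the availability correction (a flag
order is not exposed; applying it before made no qualitative difference in
our recovery experiments and the corrected density is the quantity the
threshold protects).

**Niche cells and projection.** The native niche is the set of bins with
non-zero corrected density; a *core* variant keeps the smallest set of
highest-density bins containing a fraction `q` (default 0.7 for the
sensitivity analysis) of the total density, including the bin that crosses
the boundary, with ties broken by bin index.  Predictions are restricted to
*analogue climate* — bins available in both realms — and projected back to
geography: every introduced-realm land cell whose climate falls in a niche
bin is part of the potential naturalised range.  Areas are
cos(latitude)-weighted with cell width taken at the equator.

**Validation.** Native data are split 80/20 five times (disjoint validation
folds).  For each fold the niche is rebuilt on the training data and
projected onto the native realm.  True-presence accuracy is the fraction of
validation presences falling in suitable cells.  TSS
(sensitivity + specificity − 1) is scored against 20 pseudo-absence sets per
fold, each the size of the validation set, drawn from native-realm cells in
administrative units that contain no native occurrence.  Note that with
broad-niched species the pseudo-absence pool is itself largely suitable, so
TSS is expectedly much lower than accuracy; accuracy is the primary
sensitivity measure for presence-only niches.

## Range filling

The occupied naturalised range is the union of convex hulls of the species'
naturalised occurrences, one hull per administrative unit (hulls never bridge
units).  Units with one or two points (or collinear points) get a half-cell
buffer so their occupancy is non-zero.  A raster cell counts as occupied when
its centre lies in the union.  Range filling is the area-weighted proportion
of the potential range covered by the union; niche filling is the fraction of
native-niche analogue bins that contain at least one naturalised occurrence.
Threat maps count, per cell, the species whose potential range includes the
cell but whose occupied polygons do not (a flag includes occupied cells
instead).  The recording-effort adjustment divides cell counts by the local
detection probability, floored at 0.01% (so the inflation is capped at
×10,000); detection rasters at other resolutions are resampled by nearest
neighbour.

## Landscape fragmentation

Contagion (0–100) and clumpiness (−1–1) are computed from rook-adjacency
counts with the interior double-count convention and no landscape-border
contribution; nodata cells are excluded from both proportions and adjacency
sums.  A single-class landscape has contagion 100 (complete dominance) by
convention, and clumpiness is undefined at P = 1 (raised as an error).
Clumpiness uses `G = g_ii / sum_k g_ik` and equals `(G − P)/P` when `G < P`
and `P < 0.5`, else `(G − P)/(1 − P)`; it is extent-independent and therefore
comparable across realms of different sizes, which contagion is not.

## Hierarchical beta regression

Range filling `y ∈ (0,1)` for establishment event *i* in realm *r*:

    y_i ~ Beta(mu_i * phi, (1 - mu_i) * phi)
    logit(mu_i) = b0 + sum_k b_k x_ik + u_r [+ sum_k v_kr x_ik]

with realm intercept offsets `u_r ~ Normal(0, sigma_u)` and optional
realm-varying slopes `v_kr ~ Normal(0, sigma_k)`.  Categorical covariates are
treated exactly like the realm term (per-level offsets sharing a half-Cauchy
sd).  Priors are weakly informative and centred on the null:
`Normal(0, 2.5)` on fixed effects (covariates are centred and scaled, sample
sd, before fitting), `half-Cauchy(2.5)` on group sds, `half-Cauchy(5)` on
`phi`.  Responses exactly 0 or 1 are compressed by `(y(n−1) + 0.5)/n`
(standard beta-regression practice).  An option scales covariates by two
sds instead of one for direct comparability with binary predictors.

**Sampling.** The joint posterior density is written in the package and
sampled with an affine-invariant ensemble sampler (differential-evolution
moves; group sds and `phi` on the log scale with the Jacobian included).
Defaults follow the model's original sampling plan as pooled draw counts:
10,000 burn-in and 20,000 retained draws split across ≥ 40 walkers.  Walkers
act as chains for the rank-normalised potential-scale-reduction check
(threshold 1.05 on every parameter); sampling is extended up to three times
when the check fails, after which the fit is flagged unconverged.  A fixed
seed yields identical draws.

**Diagnostics.** DIC with effective parameters `pD = mean(D) − D(mean θ)`;
WAIC and pointwise LOO from the pointwise log-likelihood (arviz); a
pseudo-R² defined as the squared sample correlation between the
posterior-mean linear predictor and the logit-transformed response; Pearson
residuals under the beta variance `mu(1−mu)/(1+phi)`.

**Significance and selection.** A parameter is significant when its
posterior mean and the 2.5th/97.5th percentiles share a sign; realms differ
on a parameter when two realms' 90% intervals are disjoint.  Model selection
is staged: (1) univariate screening with realm-varying slopes keeps
covariates with a global or realm-specific 90% effect; (2) collinear pairs
(pairwise R² above 0.5 by default) spawn alternative candidate models;
(3) a candidate that fails to converge drops its covariate with mean nearest
zero and is refitted; (4) all converged candidates within ΔDIC ≤ 5 of the
best are reported as equally plausible and the most parsimonious is
selected.  The sensitivity model regresses filling on the (logged,
standardized) number of occupied naturalised cells with the same machinery.

## The synthetic world

The generator emulates the shape of the real inputs, not their values:

* **Climate** — three Gaussian random fields (white noise convolved with a
  Gaussian kernel of configurable correlation length, rescaled to the
  requested mean/variance).  The warmest-month layer tracks the
  coldest-month layer with an offset, so the three variables have an
  effectively two-dimensional structure like real terrestrial climate, and
  an optional latitudinal gradient is available.  No attempt is made to
  mimic real covariance structure or geography.
* **Realms and admin units** — contiguous vertical bands of land split into
  a near-square grid of 100 contiguous admin blocks per realm (TDWG-level-4
  -like granularity); a one-cell sea ring bounds the lattice.
* **Species** — a bivariate Gaussian niche over (coldest-month temperature,
  annual precipitation).  Native occurrences are drawn cell-wise with
  probability proportional to niche density (so their climate-space
  distribution is density × availability, as for real records).  The *true
  suitable area* of the introduced realm uses the same one-thousandth-of-
  maximum convention as the estimator.  The introduced range is grown
  cell-by-cell (rook neighbours) from a random introduction point until a
  fraction `f_true` of the suitable cells is occupied, with at least one
  record per occupied cell — so `f_true = 1` saturates the suitable area —
  plus extra records up to the configured count (defaults: 100 native / 30
  introduced).
* **Regression data** — drawn from exactly the hierarchical beta-logit model
  above, with configurable coefficient map, per-term realm spreads, and
  precision.

## Recovery studies and their conditions

The canned experiments in `invasionfill.experiments` fix their study
conditions once:

* **Niche recovery** runs on a 200 × 200-cell world with climate correlation
  length ≈ 3 cells, species niches of sd 0.7 × the realm climate sd centred
  in the 0.4–0.6 climate quantiles, and 200 native occurrences per species.
  The world is large enough that the 100 × 100 climate space is densely
  available (as it is for real continental realms on a 10-arc-minute grid),
  and the niche breadth corresponds to broad-ranging species — the regime
  the ad hoc bandwidth rule is calibrated for.  Narrower niches are
  systematically over-estimated (kernel spread) and much broader ones
  under-estimated (no samples in the far density tail), which is a property
  of kernel support estimation generally, not of this implementation.
* **Coefficient recovery** simulates 5,000 establishment events across six
  realms from the published per-taxon point estimates (realm intercept sd
  0.3, precision φ = 15 — values in the realistic range implied by the
  reported model fits) and refits the same model.
* **Null calibration** repeats 20 independent univariate fits at n = 2,000
  with all generating coefficients zero and counts fits flagging any
  covariate significant.

Passing these tests shows the estimators are unbiased and calibrated *under
the generator's assumptions* — Gaussian niches, equilibrium occupancy of the
occupied region, perfect detection, and exchangeable realms.  They do not
speak to taxonomic error, spatial sampling bias, niche shifts, or dispersal
barriers in real data; the recording-effort adjustment and the
occupied-cell-count sensitivity model exist precisely because real data
violate these assumptions.

## Known limitations

* Only two ordination axes; species whose niche depends on the third
  principal component are mis-specified by construction.
* Cell-centre polygon–raster intersection (half-cell bias possible for very
  small hulls); hull buffering of degenerate units is a convention.
* The ensemble sampler is distributionally equivalent to, not numerically
  identical with, Gibbs-based fits of the same model; agreement is
  established by parameter recovery, not draw-by-draw.
* Real-data mode (GBIF downloads, WorldClim rasters, TDWG polygons,
  recorder-effort maps) expects the user to supply those inputs; the package
  ships no global data.
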