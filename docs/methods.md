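# Methods

`pelagichab` implements a habitat-suitability analysis for a pelagic fish
(the motivating case is yellowfin tuna caught by pelagic longlines in a
Gulf-of-Mexico-like basin) as a tested, reusable pipeline. The observation
unit is a longline *set*: a date, a position, a number of hooks `H_i`, and a
catch count `y_i`. The pipeline derives environmental covariates from
gridded fields, fits a hierarchical Bayesian count regression with spatial
and seasonal random effects, selects among competing model structures by
WAIC, and maps the fitted species–environment relationship onto a grid as
habitat suitability.

## The observation model

Catch counts are modelled with a log link and an effort offset:

```
y_i ~ NegBin(mu_i, k)   or   Poisson(mu_i)
log mu_i = log E_i + beta_0 + sum_j beta_j · poly(X_j,i) + W(s_i) + gamma[M_i]
E_i = (sum_i y_i / sum_i H_i) · H_i
```

* `E_i` is the effort offset: a known multiplicative component of the mean
  proportional to hooks, scaled so `sum(E) = sum(y)` exactly.
* `poly(X_j)` are raw powers (degree 1–3) of the standardized covariate
  (centered and scaled by the training mean/sd; the transform is stored and
  re-applied at prediction time).
* `W(s)` is a Matérn Gaussian field (nu = 1) over the study area,
  represented by the SPDE/finite-element approach: linear finite elements on
  a Delaunay triangulation turn the field into a Gaussian Markov random
  field with sparse precision `Q = tau^2 (kappa^4 C + 2 kappa^2 G + G C^-1 G)`,
  where `C` is the mass-lumped mass matrix and `G` the stiffness matrix.
  Range and marginal sd are `rho = sqrt(8)/kappa` and
  `sigma = 1/(sqrt(4 pi) kappa tau)`. The mesh uses plate-carrée degrees
  treated as planar; over a regional domain (~16°) the metric distortion is
  a few percent and is accepted (an equal-area projection can be applied
  upstream by transforming coordinates before meshing).
* `gamma[M]` is a cyclic first-order random walk over the 12 calendar
  months (month 12 adjacent to month 1), with precision hyperparameter
  `tau_s` and a sum-to-zero constraint imposed as a soft quadratic penalty
  (precision 1e6 on the sum — the posterior sum is O(1e-3) or smaller).
* The negative binomial uses the mean/size parameterization,
  `var = mu + mu^2/k`; `k -> inf` recovers the Poisson.

## Covariate construction

Two anomaly pathways are derived from each dynamic field (sea-surface
height is the primary one; SST and log10-CHL follow the same operations):

* **Spatial anomalies** (`*_sa`): per time layer, the mean over the
  study-area polygon (cell-center-in-polygon rule, unweighted cell mean;
  latitude-cosine weighting behind a flag) is subtracted from every cell.
  This removes all temporal scales and keeps only spatial gradients — the
  mesoscale signal (eddies, fronts). The operator is idempotent and linear,
  and every layer's polygon mean is exactly zero afterwards.
* **Interannual anomalies** (`*_ia`): the monthly domain-mean series is
  decomposed by OLS onto 12 calendar-month indicators plus a linear time
  term; the residuals are the interannual anomalies, assigned to every set
  by its calendar year-month. The decomposition is exactly additive
  (mean = seasonal + trend + residual to machine precision) and the trend
  slope is also reported per decade. At least 24 months are required.
  Indicators rather than harmonics keep the seasonal term exactly
  invertible; the trend is linear — the minimal choice when nothing longer
  is identifiable. Note a finite number of interannual cycles is not
  exactly orthogonal to the time term, so a strong oscillation biases the
  estimated trend slightly (the pipeline reports what the construct
  measures, not the generator's input).

Pairing averages each field over a fixed temporal window strictly before
the set day (half-open `[date - w, date)`, so covariates are causal),
block-averages to the 0.25° analysis grid (integer-ratio block means,
missing-aware), and matches each set to the nearest cell center by
great-circle distance with a deterministic lowest-lon-then-lowest-lat
tie-break and a one-cell fallback around missing cells. Records that cannot
be matched are dropped and counted; a configurable retention floor guards
against silent data loss.

## Screening and model competition

Before fitting, covariates are screened on their base (degree-1) values:
pairwise Pearson correlations and variance inflation factors
(`1/(1-R^2_j)`). Pairs with `|r| > 0.6`, and covariates with GVIF > 3
(paired with their strongest correlation partner), are *forbidden* from
entering the same structure. The structure enumerator generates all subsets
of the candidate pool without a forbidden pair, crossed with per-covariate
polynomial degree (1–3) and likelihood family (NB, Poisson); bottom depth
is carried in every structure, and all structures share the offset, the
spatial field and the cyclic month effect. A zero-catch-fraction check
advises (threshold 0.25) whether a zero-inflated family would be needed;
zero-inflated likelihoods themselves are out of scope.

Model selection fits every structure on the same data and mesh and ranks by
WAIC, `-2(lppd - p_waic)`, computed from S posterior draws of the pointwise
log-likelihoods (`p_waic` uses the sample variance with denominator S-1).
Ties break to the lexicographically smaller structure id; failed fits are
recorded with their reason and excluded.

## Inference

A nested Laplace scheme (deliberately simpler than full INLA, adequate at
the accuracy the recovery tests require):

1. For a hyperparameter point `theta = (log kappa, log tau, log tau_s,
   log k)`, the latent field `(beta, W, gamma)` is approximated by a
   Gaussian at its conditional mode, found by Fisher scoring (expected
   information, step-halving on the penalized log-likelihood) on the joint
   precision `Q_prior(theta) + B' W B`.
2. The Laplace-approximate log marginal posterior of `theta` is maximized
   by Nelder-Mead (default budget 60 evaluations — see the note on
   identifiability below). The SPDE prior log-determinant is evaluated in
   O(m) per point from the precomputed generalized eigenvalues of
   `C^{-1/2} G C^{-1/2}`.
3. The posterior over `theta` is integrated on a small axis design: the
   mode plus one point at ± a curvature-scaled step per free dimension,
   with weights chosen so the design reproduces the mean and per-axis
   variance of the matched Gaussian exactly (center weight `1 - d/z^2`,
   axis weights `1/(2 z^2)`, `z = max(1.3, sqrt(d))`). `hyper_method="eb"`
   uses the mode only.
4. Posterior summaries mix over the design points; S (default 250) draws
   from the Gaussian mixture supply WAIC and all gridded predictions. The
   seed governs only these draws; everything else is deterministic given
   the settings.

Priors: fixed effects N(0, 31.6²); seasonal precision and NB size
Gamma(1, 5e-5) (essentially flat); `log kappa`, `log tau` wide normals
(sd 2) centered at a range of one fifth of the mesh extent and unit
marginal sd. All are configurable through `Priors`.

**Known limitation — range/overdispersion confounding.** A short-range,
large-sd spatial field can mimic negative-binomial overdispersion. With
wide SPDE priors and a long optimizer run the marginal posterior can drift
to that ridge (range below the mesh edge length, NB size biased low); the
latent field and the fixed effects remain well recovered, but the
hyperparameters are then not separately interpretable. Moderately
informative priors (e.g. `log_kappa_sd = log_tau_sd = 0.5`) recover range,
sd and size jointly. The defaults keep the wide priors and a bounded,
deterministic optimizer budget.

## Prediction and habitat suitability

Suitability maps evaluate the linear predictor at unit effort on every
polygon cell inside the mesh hull: covariates come from that month's
rasters (standardized with the training transform; values beyond 3
training sds raise an extrapolation advisory but are still predicted), the
spatial field is interpolated to cell centers by the barycentric projector,
and the month effect is added. The posterior median of `mu = exp(eta)` is
taken as `exp(median eta)` (exp is monotone, so this is exact and does not
inherit the even-sample-median artifact of averaging two middle draws);
the sd raster is the posterior sd of `mu`. Maps are scaled by the maximum
posterior median over the scaling scope — jointly across the 12
climatology months (so months are comparable), or across all maps of a
scenario set; per-map scaling is available. "High-quality habitat" (HQH)
is the percentage of polygon cells with suitability ≥ 0.6. Suitability is
the expected catch rate, not a predictive count quantile, so it does not
inherit NB sampling noise. Climatologies average each calendar month's
rasters across years with the interannual anomaly fixed at 0; yearly
scenarios use that year's rasters and realized monthly residuals.

## The synthetic study

The generator produces the study conditions the analysis assumes, with
ground truth emitted alongside (never hidden), so every acceptance check is
parameter recovery rather than comparison to irreproducible archival data:

* **Sea-surface height** (cm): background 55 + seasonal cosine (amplitude
  8 cm, peak September) + linear trend (4.8 cm/decade) + interannual
  sinusoid (amplitude 5 cm, period 24 months) + drifting Gaussian eddies
  (3 anticyclonic +25 cm, 3 cyclonic −25 cm, radius 1.5°, westward drift
  0.5°/month, seasonally modulated intensity). The per-layer domain mean of
  the eddy component is removed, so the injected curve *is* the layer-mean
  series and the two anomaly pathways separate exactly.
* **SST / CHL**: SST is an affine function of standardized SSH plus noise
  at a requested correlation; CHL is lognormal (strictly positive, so the
  log transform is exercised).
* **Bathymetry**: a linear shelf ramp from the domain boundary to a flat
  3500 m basin (shelf width 2°) with small seeded noise on the ramp.
* **Fishery**: sets uniform (optionally clustered) in the polygon over
  2012–2019, hooks uniform in 450–750; catches drawn from the observation
  model above with defaults intercept 2.6, cubic-style effect vectors on
  `adt_sa`, depth and `adt_ia`, spatial sd 0.5 / range 4°, a two-peaked
  seasonal curve (mid-summer and early-winter highs), NB size 2.2. These
  defaults put the zero-catch fraction near 4–5% and set-level catches in
  the 0–150 range, the regime the analysis is designed for.
* The generator's effort is `E = H/mean(H)` (the pipeline offset cannot be
  formed before catches exist); the pipeline offset differs by the constant
  `log(c · mean(H))`, `c = sum(y)/sum(H)`, absorbed by the fitted intercept
  and reported by `simulate_study` as `intercept_shift`.

What the generator does *not* emulate: quasi-geostrophic dynamics, real
Gulf bathymetry, cloud-masked CHL gaps, preferential sampling of good
habitat by the fleet, and along-line set geometry. Passing recovery tests
therefore demonstrates the statistical machinery, not robustness to those
real-data features.

## Problem sizes and numerical choices

The shipped checks use desk-scale sizes chosen as representative rather
than exhaustive: parameter recovery at n = 2000 sets on a ~320-vertex mesh
(20 replicates), model competitions at n = 600 on a coarse mesh, scenario
contrasts at n = 400 on a 0.5° grid. Fisher scoring converges at relative
tolerance 1e-6 with an iteration cap of 100 (exceeding it raises, with the
count of failing hyper points). The linear predictor is clipped at ±30
inside the likelihood to keep `exp` finite; curvature floors (1e-10) guard
degenerate weights. Exact WAIC ties in a leaderboard break
lexicographically. Meshes drop exactly degenerate (zero-area) slivers that
arise from collinear boundary points; the projector clips barycentric
coordinates at 0 and renormalizes, so locations on triangle edges are
handled exactly.
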