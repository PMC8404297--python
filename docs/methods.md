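# Methods

This document records the statistical model, the cohort conventions, the
synthetic-data generator and the numerical choices made in `comap`, together
with their rationale and limitations.

## Observation model

For areas `i = 1..n` and diseases `j = 1..J` (default: AMI, stroke, AF),

```
Y_ij | mu_ij ~ Poisson(mu_ij),    mu_ij = E_ij exp(beta_j + phi_ij)
```

where `E_ij` is the expected count under internal standardization and
`exp(beta_j + phi_ij)` is the area- and disease-specific relative risk. The
posterior SIR reported for each cell is `mu_ij / E_ij` per draw, summarized
by its median and a central credible interval. Cells with `E_ij = 0` and
`Y_ij = 0` are outside the model and skipped; `E_ij = 0` with `Y_ij > 0` is
an input error and raises.

## Expected counts: internal standardization

Person-years at risk are accumulated per area and stratum, with strata
defined by sex (female, male), age group (30–59, 60–69, 70–79, 80+) and
income group (Low, Medium, High) — 24 strata, indexed
`k = sex*12 + age*3 + income`. National stratum rates are
`R_jk = (national cases)/(national person-years)`, and

```
E_ij = sum_k R_jk T_ijk
```

This makes `sum_i E_ij = sum_i Y_ij` hold exactly per disease, which the
tests assert on every synthetic dataset.

## Cohort engine conventions

- **Closed cohort**: a person enters follow-up only if alive, resident, at
  least 30 years old and free of the disease in question on the study start
  date (default window 2014-01-01 to 2015-12-31). People who turn 30 during
  the window are not enrolled.
- **Half-open intervals** `[entry, exit)`; administrative censoring at the
  day after the window end. Person-time is `days / 365.25`.
- **Splitting**: each interval is split at every 1 January (the yearly area
  and income assignments change there) and at every age-group boundary
  birthday, defined as `birth + ceil(a * 365.25)` days for lower bound `a`.
  A person aged ~59.5 at the start therefore contributes exactly
  `182/365.25` PY to 30–59 and `548/365.25` PY to 60–69 over the two-year
  window (the nominal 0.5/1.5 split, exact under the day-count convention).
- **Ties at exit** resolve with precedence event > death > emigration >
  administrative censoring. An event on the start date itself counts as an
  incident case with zero person-time; a death on the start date contributes
  neither person-time nor a case and is dropped.
- Cases are attributed to the area, income and age group in force at the
  exit date.

## Spatial model: coregionalized Leroux CAR fields

The random effects follow a linear model of coregionalization,

```
phi_i. = A u_i.,    Sigma = A A'
```

with `A = diag(sd) chol(R)` for a correlation matrix `R`, and each latent
column `u_.l` an independent Leroux CAR field with unit conditional scale:

```
u_.l ~ N(0, Q(rho_l)^-1),    Q(rho) = rho (D - W) + (1 - rho) I
```

`W` is the binary rook-contiguity matrix and `D` its degree diagonal.
`Q(rho)` interpolates between independence (`rho = 0`) and the intrinsic
CAR (`rho -> 1`) and is positive definite for `rho` in `[0, 1)`. Its
log-determinant is computed from the precomputed eigenvalues of `D - W`
(`log det Q = sum log(rho lam_m + 1 - rho)`), verified against a direct
`slogdet` oracle to 1e-8.

Model variants:

- **M1**: disease-specific `rho_j`, full correlation matrix `R`.
- **M2**: one shared `rho`, so the covariance is separable; the
  between-disease conditional correlation at collocation is exactly
  `Sigma_jk / sqrt(Sigma_jj Sigma_kk)`.
- **M3**: diagonal `Sigma` and disease-specific `rho_j` — independent
  univariate maps, used as the comparison baseline.

Island areas must be ferry-linked before fitting: a degree-0 area's
conditional variance degenerates as `rho -> 1`, so disconnected maps are
rejected rather than silently smoothed.

## Priors

- `beta_j ~ N(0, precision 0.1)` — weakly informative on the log-risk scale.
- `sd_j ~ U(0, 10)` — generous for log-relative-risk scales (observed
  posterior sds are ~0.2); the sensitivity analysis widens it to `U(0, 100)`.
- pairwise correlations `~ U(0, 1)`, restricted to positive-definite `R` by
  rejection — cardiovascular diseases share risk factors, so negative
  spatial correlations are excluded a priori.
- `rho ~ U(0, 1)`.

Because the uniform densities are flat, the `sd` upper bound only enters
the Metropolis ratio through its support: if no proposal ever exceeds 10,
the chains under bounds 10 and 100 are bit-for-bit identical and the
sensitivity delta is exactly zero. That is the observed behaviour on the
default dataset, and it is the strong form of "results not sensitive to the
prior bound".

## Sampler

Metropolis-within-Gibbs, per iteration and disease:

1. **Latent field** `u_.j`: single-site random-walk Metropolis, vectorised
   over graph-colouring classes (same-colour areas are conditionally
   independent given the rest, so a whole colour class can be
   accepted/rejected elementwise in one pass without changing the
   stationary distribution). The CAR quadratic forms `u'(D-W)u` and `u'u`
   are cached and updated incrementally.
2. **Intercept and scale** `beta_j`, `sd_j`: random-walk Metropolis, the
   scale on the log scale with its Jacobian.
3. **Correlations** (M1/M2) and **rho**: random-walk Metropolis on the
   logit scale with Jacobians; proposals outside the support or breaking
   positive definiteness are rejected.

Step sizes adapt by Robbins–Monro towards 0.44 acceptance during burn-in
only, and are frozen afterwards, so the post-burn-in kernel is a fixed
valid MCMC kernel. Default chains: 2 × 20,000 iterations, burn-in 10,000,
thinning 10 (2,000 retained draws).

Determinism and stream design: every update block draws from a
`SeedSequence([seed, chain, tag])` stream, with per-disease tags for the
blocks that touch a single disease and a shared tag for the correlation and
shared-`rho` blocks. A consequence used as a structural test: an M3 joint
fit equals three univariate fits draw-for-draw, because each disease
consumes exactly its own stream.

Hot loops (site updates, intercept/scale updates, correlation updates, rho
acceptance ratios) are compiled with numba when available; all random
numbers are still drawn in numpy and passed in, so compiled and
interpreted runs produce identical chains.

Validation harness: `MCARModelSpec(likelihood="gaussian")` replaces the
Poisson likelihood by `y ~ N(beta + phi, tau^2)`, making the latent field's
full conditional Gaussian in closed form; combined with per-block update
switches this lets the production sampler be checked against exact
moments. A 1-D quadrature oracle checks the intercept posterior the same
way.

## Diagnostics and model choice

- **Geweke z**: first 10% vs last 50% means, spectral variance with a 4%
  lag window. The statistic is only approximately N(0,1) at these window
  sizes (mildly overdispersed on iid chains), which the tests account for.
- **ESS**: `N / (1 + 2 sum rho_k)` with Geyer initial-positive-sequence
  truncation, summed over chains.
- **DIC** = `Dbar + pD`, `pD = Dbar - D(mean of mu)`, computed from the
  stored per-draw fitted means. Lower is better; near-ties (|delta| < 1)
  resolve to the simpler model (M2 before M1 before M3).

## Synthetic data

- **Map**: 7 × 14 rook lattice (98 areas) with seven designated island
  cells detached and ferry-linked back, exercising the island machinery in
  several neighbourhoods.
- **Aggregated generator**: exact Leroux draws via Cholesky of `Q(rho)`,
  `phi = u chol(Sigma)'`, Poisson counts. Reference generating values:
  `rho = 0.67`, correlations `(0.47, 0.42, 0.65)` — the posterior regime the
  model targets in cardiovascular applications — and marginal field sd 0.2,
  which on this lattice yields a latent SIR spread of roughly 0.75–1.35,
  matching published smoothed SIR ranges. `E = 200` per cell puts the data
  in the information regime of municipal counts.
- **Cohort generator**: ages uniform 18–95 at start, yearly area/income
  reassignment (Markov moves), constant death/emigration hazards by
  starting age group, pre-study first diagnoses planted with age-scaled
  prevalence (to exercise prevalent-case exclusion), and in-study events
  from piecewise-constant hazards split at exactly the year and age-group
  boundaries the downstream stratification uses — so the cohort engine's
  assumptions hold by construction and rate recovery is testable. Stratum
  rates are patterned on nationwide cardiovascular incidence (steeply
  increasing with age, male > female, decreasing with income) at a scale
  suitable for a 10,000-person cohort.

## Published-margins fixture

`comap.reference` carries the aggregated characteristics (cases and
person-years by total, sex, age group and income group) of the Danish
nationwide 2014–2015 cohorts of incident AMI, stroke and AF among adults
30+, plus the published smoothed SIR ranges. The underlying register data
are access-restricted; the margins serve as an aggregated input for
crude-rate computation (reproduced exactly at one decimal) and for
presentation checks such as the SIR-to-percent conversion
(0.76 → −24%, 1.35 → +35%).

## Limitations

- The synthetic lattice is a stylized stand-in for a real municipal map;
  degree distributions and island placement only mimic the mechanics, not
  the geography.
- The cohort generator uses constant death/emigration hazards from the
  starting age group and ignores within-year ageing of those hazards.
- Municipality-specific conditional correlations under disease-specific
  `rho` (M1) are computed but marked experimental: summary conventions for
  that quantity vary.
- DIC is the only model-choice criterion implemented (matching standard
  practice for these models); WAIC/LOO are out of scope.
- With 98 areas and E ≈ 200, the data only weakly identify `rho`; its
  posterior is wide, and recovery experiments should be read at the
  replicate level rather than per dataset.
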