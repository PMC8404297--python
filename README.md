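# comap

Joint Bayesian disease mapping of acute myocardial infarction (AMI), stroke
and atrial fibrillation (AF) incidence across small areas, from
individual-level event records to smoothed standardized incidence ratio
(SIR) maps, between-disease correlations and model comparison.

## What it does

Cardiovascular diseases share risk factors, so their geographic patterns are
correlated; mapping them jointly borrows strength both across neighbouring
areas and across diseases. `comap` implements the full chain:

1. **Geography** — build a symmetric neighbour structure over areas (from an
   edge list or polygon GeoJSON, rook contiguity), with explicit handling of
   island areas that are ferry-linked to the mainland.
2. **Cohort engine** — turn person-level records (birth, death, emigration
   and first-diagnosis dates, plus yearly area/income assignments) into
   person-years at risk and incident case counts per area and stratum
   (2 sexes × 4 age groups × 3 income groups), following each person through
   calendar-year and age-group boundary crossings. Expected counts come from
   internal standardization: `E_ij = Σ_k R_jk T_ijk` with national stratum
   rates `R`, so `Σ_i E_ij = Σ_i Y_ij` exactly.
3. **Model** — a multivariate Poisson disease-mapping model
   `Y_ij ~ Poisson(E_ij exp(β_j + φ_ij))` whose spatial random effects
   follow a linear model of coregionalization over Leroux CAR latent
   fields. Three variants: **M1** (disease-specific spatial dependence ρ_j,
   correlated diseases), **M2** (shared ρ, separable covariance), **M3**
   (independent diseases). Fitting is by Metropolis-within-Gibbs with
   adaptive random-walk proposals, fully deterministic given a seed.
4. **Diagnostics** — Geweke z-scores, effective sample sizes,
   autocorrelations and DIC (deviance information criterion) for model
   choice.
5. **Results** — posterior SIR surfaces with credible intervals and
   significance classes, between-disease conditional correlations, map
   export (CSV / GeoJSON / PNG) and a prior-sensitivity rerun.

A synthetic data generator produces both aggregated counts (with known
ground-truth parameters, for recovery experiments) and individual-level
cohorts (with the exact piecewise-constant hazard structure the cohort
engine assumes), on a default 98-area lattice map with seven
ferry-linked islands.

The package also carries, as an aggregated input fixture, the published
characteristics (cases and person-years by sex, age group and income group)
of the Danish nationwide 2014–2015 cohorts of incident AMI, stroke and AF
among adults aged 30+ (`comap.reference`); the crude-rate machinery
reproduces every published incidence rate from them exactly at one decimal.

## Worked example

```python
from comap.pipeline import RunConfig, run

manifest = run(RunConfig(seed=0, outdir="results/run"))
print(manifest["dic"], manifest["selected_model"])
```

Running the bundled driver scripts on the default synthetic dataset
(98 areas, E ≈ 200 expected cases per cell, generating spatial dependence
ρ = 0.67 and between-disease correlations 0.47 / 0.42 / 0.65):

```text
$ python analysis/04_fit_models.py
DIC by model:
  M1: 2582.85
  M2: 2582.31
  M3: 2626.6
selected model: M2

$ python analysis/05_results.py
selected model: M2

smoothed SIR range per disease:
  AF: 0.66 to 1.34 (-34% to +34% versus the national level)
  AMI: 0.69 to 1.44 (-31% to +44% versus the national level)
  stroke: 0.68 to 1.36 (-32% to +36% versus the national level)

between-disease correlations (posterior median [95% CI]):
  AMI-stroke: 0.71 [0.52, 0.84]
  AMI-AF: 0.37 [0.12, 0.57]
  stroke-AF: 0.74 [0.57, 0.86]

spatial dependence:
  rho: 0.62 [0.36, 0.86]
```

The shared-ρ model M2 wins on DIC, the independent model M3 loses clearly,
and the recovered ρ and correlations bracket the generating values.

A `comap` command-line interface wraps the same pipeline
(`comap run-all --seed 0 --outdir results/run`, plus `simulate`, `cohort`,
`fit`, `diagnose`, `report` subcommands).

## Reproduction

Everything is seeded; the numbered scripts under `analysis/` re-create all
artifacts under `results/`:

```sh
python analysis/01_build_geography.py    # adjacency structure of the map
python analysis/02_simulate_cohort.py    # individual-level synthetic cohort
python analysis/03_cohort_tables.py      # crude incidence-rate tables
python analysis/04_fit_models.py         # fit M1/M2/M3, DIC model choice
python analysis/05_results.py            # SIR surfaces and correlations
python analysis/06_sensitivity.py        # prior-sensitivity rerun
```

`scripts/acceptance.py` recomputes the headline quantities end to end and
writes them as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the model, its priors, the cohort conventions and
the numerical choices.
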