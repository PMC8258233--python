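# avisurvey

Analysis pipeline for dual-method avian biodiversity surveys that pair
6-minute point counts (PC) with autonomous recording units (ARU) across
mountain habitat gradients. The package provides:

- **`avisurvey.survey_data`** — the five-table survey data model (sites,
  site-surveys, detections, species→family lookup, known-community
  inventory), CSV readers/writers with validation, design tallies,
  incidence-frequency construction, family/habitat modeling filters, and
  canopy-on-elevation residuals.
- **`avisurvey.diversity`** — incidence-based Hill-number rarefaction and
  extrapolation (q = 0, 1), sample-coverage estimation, standardization of
  estimates at a common coverage target (default 97%), the Chao2 richness
  asymptote, bootstrap 84%/95% confidence intervals, and the
  84%-CI-overlap method comparison rule.
- **`avisurvey.occupancy`** — family-level single-season occupancy-detection
  models: quadratic date/hour/canopy survey-condition effects, a first-order
  Markov (within-day lag) detection covariate, a method effect with the
  seven method-interaction combinations (nine candidate models), maximum
  likelihood fitting with analytic gradients, MacKenzie–Bailey bootstrap
  overdispersion (ĉ), QAIC model selection, and delta-method detection
  curves with ĉ-inflated intervals.
- **`avisurvey.method_comparison`** — single-method species lists, Fisher
  exact method-bias tests, and percent-of-known-community summaries.
- **`avisurvey.efficiency`** — protocol time-cost model (shared visitation
  for mixed protocols) and bootstrap cost-efficiency curves with Pareto
  frontier extraction.
- **`avisurvey.synthetic_data`** — a seeded generator reproducing the
  two-region study design at full scale (e.g. 700 ARU site-surveys and
  129 point-count sites in the northern region), with species communities
  that include zero-vocalization species and within-day Markov
  autocorrelation.
- **`avisurvey.pipeline` / `avisurvey.cli`** — end-to-end orchestration with
  per-stage seeds and a reproducible JSON summary.

## CLI

```sh
# generate a synthetic two-region dataset
avisurvey simulate --scenario BC --seed 1 --out data/

# coverage-standardized diversity for one assemblage
avisurvey diversity --data data/ --habitat montane --method ARU \
    --coverage 0.97 --q 0 --q 1 --boot 200 --seed 2 --out div.csv

# nine-model occupancy selection for one family
avisurvey occupancy --data data/ --family Parulidae --boot-gof 1000 --seed 3

# Fisher-exact method-bias table
avisurvey compare --data data/ --alpha 0.05

# protocol cost-efficiency curves
avisurvey efficiency --data data/ --habitat alpine --max-aru 15 --max-pc 3 \
    --reps 10000 --seed 4 --out eff.csv

# full pipeline from a YAML config
avisurvey run config.yaml
```

A minimal `config.yaml`:

```yaml
scenario: BC
out_dir: out
stages: [simulate, diversity, compare, efficiency]
seeds: {simulate: 1, diversity: 2, occupancy: 3, efficiency: 4}
efficiency_reps: 1000
```

## Data layout

`sites.csv`, `surveys.csv`, `detections.csv`, `families.csv`,
`known_community.csv` — comma-separated, UTF-8, ISO-8601 dates, headered.
One row of `surveys.csv` is one *site-survey*: a single 6-minute observation
unit (a point-count round or one analyzed ARU window). Duplicate
`(survey_id, species)` detection rows collapse to a single incidence on read.
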