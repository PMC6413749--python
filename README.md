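# dysregkit

Physiological-dysregulation analysis for longitudinal, multispecies
biomarker cohorts. The core score is the Mahalanobis distance of an
observation's biomarker profile from a reference population's multivariate
mean — a covariance-aware measure of deviation from homeostasis. Around it,
the package provides:

- **Cohort I/O and filtering** (`dysregkit.cohort_io`): validated CSV
  ingestion, adult filtering by species maturation age, cell-wise
  plausibility screening, variable or fixed marker-panel selection, Newick
  phylogeny loading.
- **Transforms and standardization** (`dysregkit.transform`): per-marker
  log/sqrt/identity transform selection by Shapiro–Wilk W on the reference
  sample, z-scoring against reference moments, domain-violation policies.
- **Reference populations** (`dysregkit.references`): species-self,
  cross-species, and seeded balanced multispecies ("combined") references,
  all built from each individual's first (youngest) observation; JSON
  round-trip with full provenance.
- **Scoring** (`dysregkit.scoring`): Cholesky-based Mahalanobis distances
  (no explicit inverse), minimal diagonal shrinkage for ill-conditioned
  covariances, within-species score standardization, emergence diagnostics.
- **Association models** (`dysregkit.models`): per-species mixed models of
  the standardized score on age × sex, body-mass models, and subsequent
  mass-change-rate models (statsmodels REML).
- **Survival** (`dysregkit.survival`): counting-process interval coding
  (next-visit / death / 0.25-year stop rules, event only on the final visit
  of a confirmed death) and Cox proportional-hazards fits with age as the
  timescale (lifelines, Efron ties).
- **Conservation analysis** (`dysregkit.conservation`): species × species
  cross-reference correlation matrix, patristic distance matrix, and a
  Spearman matrix correlation with Mantel-style permutation significance.
- **Synthetic cohorts** (`dysregkit.simulate`): seeded multispecies
  generator with phylogeny-scaled divergence of marker means/covariances,
  age-inflated dispersion, score-linked Gompertz mortality, and mass
  trajectories — with recorded, regenerable ground truth.

## CLI

```bash
# generate a synthetic cohort
dysregkit simulate --config sim.yaml --out cohort.csv --truth truth.json

# score a cohort against a serialized reference
dysregkit score --cohort cohort.csv --reference ref.json --out scores.csv

# full pipeline from one config (simulate/ingest -> filter -> score ->
# models -> survival -> conservation), with a run manifest
dysregkit run --config run.yaml
```

A minimal `run.yaml`:

```yaml
outdir: results/run1
seed: 1
simulate:
  n_species: 5
  n_ids: 100
  p_markers: 8
  mean_visits: 2.5
  hazard_baseline: 0.02
  beta_dm: 0.4
n_permutations: 999
```

Exit codes: 0 success, 2 configuration error, 3 stage failure.

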