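# bruvkit

A toolkit for designing and analysing baited remote underwater video (BRUV)
surveys, from spatially balanced sampling design through frame-level
annotations to ecological indices, driver models and species rarefaction.
A seeded synthetic-seascape generator simulates the full observation process
with recorded ground truth, so every stage of the pipeline is testable
without field data.

## What it does

- **`bruvkit.synthetic`** — seeded artificial archipelago (bathymetry,
  four benthic sub-habitats, inhabited-island points) and an observation
  simulator: per deployment × species latent MaxN from a log-linear
  negative-binomial model with habitat-specific depth effects and a
  hyperabundant shoaling mixture, frame counts thinned so MaxN is exact by
  construction, lognormal body lengths with depth/remoteness/exposure
  effects, and partial measurability.
- **`bruvkit.design`** — GRTS (generalized random tessellation stratified)
  sampling on a discrete cell frame: hierarchical quadrant-recursive
  addresses with per-node randomized digit permutations, systematic
  selection (exactly equal inclusion probability within stratum), reverse
  hierarchical ordering, a greedy skip-and-replace minimum-spacing rule,
  and a Voronoi-mass spatial balance diagnostic.
- **`bruvkit.ingest`** — validated reading of frame-level annotation and
  deployment tables, MaxN computation (single-frame maximum, earliest-frame
  tie-break), and the demersal/benthic trait filter.
- **`bruvkit.indices`** — per-deployment richness, relative abundance
  (summed MaxN), Shannon diversity (natural log), dispersion index, and
  biomass via `a·L^b` length–weight conversion with a tiered proxy-length
  cascade (measured-in-sample → sub-habitat mean → study mean → registry
  reference; family-level taxa use the study family mean; mono-gear
  deployments skip the in-sample tier). Habitat contrasts use
  Mann–Whitney, Kruskal–Wallis and Dunn (Bonferroni) tests.
- **`bruvkit.covariates`** — Horn 3×3 slope/aspect with buffer statistics,
  ruggedness (depth range), exposure as angular distance from due west
  (0–180°), remoteness as minimum island distance, and a Pearson + VIF
  collinearity screen with optional iterative auto-drop.
- **`bruvkit.spatial`** — 1-km² flat-top hexagonal aggregation of indices,
  4-nearest-neighbour spatially lagged response, and Moran's I with a
  seeded permutation test.
- **`bruvkit.models`** — a-priori GLM candidate sets (null, singles,
  habitat interactions, depth+relief, optional additive pairs) fitted as
  Poisson / negative-binomial (profile-likelihood dispersion) / gamma /
  Gaussian GLMs, ranked by AICc with Akaike weights and
  deviance-explained pseudo-R².
- **`bruvkit.rarefaction`** — incidence-based interpolation
  (hypergeometric expectation), Chao2 asymptote, extrapolation, and
  percentile bootstrap confidence bands.
- **`bruvkit.pipeline`** — TOML-configured end-to-end runner with
  plain-file handoffs and a deterministic run-report hash.

## CLI

```bash
bruvkit design --strata frame.csv --n Reefs=200,Sediments=100 \
    --min-dist 200 --depth 0:40 --seed 1 -o plan.csv
bruvkit maxn --annotations ann.csv --deployments dep.csv -o maxn.csv
bruvkit indices --maxn maxn.csv --annotations ann.csv \
    --deployments dep.csv --lw lw.csv -o indices.csv
bruvkit covariates --bathy bathy.asc --islands islands.geojson \
    --deployments dep.csv --buffer 200 -o cov.csv
bruvkit rarefy --maxn maxn.csv --tmax 1500 -o curve.csv
bruvkit run --config run.toml        # full synthetic pipeline
```

A minimal `run.toml`:

```toml
[run]
seed = 1
output_dir = "out"
n_per_stratum = {Reefs = 200, Sediments = 100}
min_dist = 200.0
depth_range = [0.0, 40.0]
n_species = 30
n_frames = 100
```

## Notes and conventions

- Shannon diversity uses natural logarithms.
- Exposure is 0° when the mean buffer aspect faces due west (270°) and
  180° when due east; aspect is aggregated by circular (vector) mean.
- Pseudo-R² is deviance explained (1 − D_model/D_null); the
  negative-binomial shape and gamma/Gaussian dispersion each count as an
  estimated parameter in AICc.
- The spatial lag is computed from the observed response with equal 1/k
  weights over the k = 4 nearest neighbours.
- One root seed expands into fixed per-stage child seeds; identical seeds
  give byte-identical outputs.
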