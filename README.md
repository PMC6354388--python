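# geosurvey

Bayesian geo-additive analysis of a binary outcome in two-wave clustered
household survey data. The package provides, end to end:

- **Region graphs** (`geosurvey.region_graph`) — BayesX-style `.gra`
  adjacency files (read/write, labels or 1-based indices), two-column edge
  lists, connected components, and the intrinsic-CAR precision matrix
  (graph Laplacian) used by the structured spatial prior. Stylized 11- and
  14-region fixture graphs ship in `src/geosurvey/data/`.
- **Synthetic surveys** (`geosurvey.synthetic`) — a two-stage DHS-like
  generator (clusters within regions, 21 households per cluster, all women
  aged 15–49 interviewed) with a fully known ground truth: fixed effects,
  a smooth nonlinear age effect, and structured + unstructured region
  effects, including the wave-2 subdivision of regions.
- **Descriptives** (`geosurvey.descriptive`) — unweighted prevalence
  tables, cumulative age-at-cutting distributions, baseline characteristic
  tables, and unadjusted marginal odds ratios with Wald intervals
  (Haldane–Anscombe correction on zero cells, flagged).
- **The estimator** (`geosurvey.model`) — a Bayesian geo-additive binary
  regression: dummy-coded fixed effects, penalized cubic B-splines with a
  second-order random-walk prior, an intrinsic-CAR structured region
  effect and an i.i.d. unstructured one, fitted by a data-augmentation
  Gibbs sampler (exact Pólya-Gamma draws for the logit link, Albert–Chib
  truncated normals for probit). Sum-to-zero constraints are enforced at
  every iteration by re-centering, with removed means absorbed into the
  intercept. Inverse-gamma(0.001, 0.001) hyperpriors by default.
- **Posterior reporting** (`geosurvey.summarize`) — posterior odds-ratio
  tables (median of exponentiated draws, equal-tailed intervals),
  credible curve bands (default 80%), total residual spatial effects with
  white/grey/black significance classification, harmonized between-wave
  comparisons (subdivided regions merged by unweighted averaging), a
  stepwise age-effect sensitivity sweep, and choropleth export (GeoJSON in,
  PNG/SVG out; tabular fallback without geometry).
- **Pipeline** (`geosurvey.cli`, `geosurvey.pipeline`) — a YAML-configured
  `simulate → describe → fit → summarize → compare` driver writing a
  checksummed JSON manifest. The two waves are always fitted separately.

## CLI

```sh
geosurvey simulate --seed 1 --wave 1 --out wave1.csv --truth-out truth.json
geosurvey descriptive --data wave1.csv --by region --covariate wealth --reference richest
geosurvey fit --data wave1.csv --seed 1 --iterations 12000 --burn-in 2000 --thin 10 --out draws/
geosurvey summarize --samples draws/ --level 0.95 --out summary
geosurvey compare --wave1 prev1.csv --wave2 prev2.csv --region-map map.json --out trend.csv
geosurvey run --config config.yaml     # full pipeline + manifest
geosurvey export-graph --graph fixture14 --out senegal14.gra
```

A minimal `config.yaml`:

```yaml
seed: 1
output_dir: out
graph: fixture11          # or a .gra path; fixture11 auto-attaches the
waves: [1, 2]             # three wave-2 region splits
design: {clusters_per_region: 34, households_per_cluster: 21}
model:
  fixed:
    - {field: urban, reference: 1}
    - {field: wealth, reference: richest}
  nonlinear:
    - {field: age, n_inner_knots: 20, degree: 3}
mcmc: {iterations: 12000, burn_in: 2000, thin: 10}
report: {nominal_level: 0.95, curve_level: 0.80}
```

## Notes

- MCMC defaults are 12,000 iterations / 2,000 burn-in / thin 10; the test
  suite's recovery replicates run deliberately shortened chains
  (800/250/2 at n ≈ 4,000) to stay inside a desk-scale time budget.
- The shipped region graphs are stylized fixtures built from a political
  map, not authoritative geography; polygon handling is out of scope.
- Survey weights, design-based variances and joint two-wave fits are
  intentionally not implemented.
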