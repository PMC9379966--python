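# geotwin

Geographically weighted twin variance-component modelling: estimate
additive-genetic (A), shared-environmental (C, or dominance D) and
non-shared environmental (E) influences on a standardized trait at many map
locations. Every twin pair contributes to the estimate at every target
location through a weighted full-information maximum-likelihood (FIML)
objective, with weight `1 / d(x, x_i)^p` decaying in the Euclidean distance
between the pair and the target (default `p = 0.5`). Mapping A across
locations surfaces gene-by-geography interaction; mapping E surfaces
location-dependent environmental influence.

Because the registry cohorts this kind of analysis is usually run on are
access-restricted, the package ships a first-class synthetic-cohort module:
geographically embedded twin pairs drawn from aetiology fields with known,
location-varying `a²(x), c²(x), e²(x)` and trait mean, so every stage of the
pipeline is testable against ground truth.

## Modules

| module | contents |
| --- | --- |
| `geotwin.model_core` | twin ACE/ADE model: expected covariances, per-pair FIML log-likelihoods (incomplete pairs contribute univariate marginals), weighted objective, L-BFGS-B fit over path coefficients, observed-information/delta-method 95% CIs, quantitative sex-limitation model with LRT |
| `geotwin.spatial_weights` | inverse-power-distance weights with distance flooring, Kish effective sample sizes per zygosity group |
| `geotwin.space_engine` | phenotype standardization, target construction (region centroids or seeded k-means density-representative points), per-location weighted fits, weighted-mean trait maps, historical-location sensitivity runs |
| `geotwin.synthetic_data` | aetiology fields (homogeneous / step / gradient), settlement-mixture location sampling, cohort simulation (incl. sex-limited variant), skew warp, region/snapshot helpers |
| `geotwin.mapping_viz` | winsorized (4%) diverging colour scale, point maps + matching histograms, colour-table export |
| `geotwin.io_cli` | cohort/target CSV dialects (bit-exact round trip), lon/lat → local planar projection, YAML run config, CLI |

## CLI

```sh
# simulate a cohort from a known step field
geotwin simulate --field step --n-pairs 8000 --seed 11 -o cohort.csv

# fit the weighted model at 100 density-representative targets
geotwin fit --cohort cohort.csv --k-targets 100 --model ACE --p 0.5 -o results/

# render the genetic-variance map and histogram
geotwin map --results results/space.csv --component a2_raw -o maps/

# historical-location sensitivity (snapshot columns x_<label>, y_<label>)
geotwin sensitivity --cohort cohort.csv --snapshots age9,age12 -o sens/
```

`fit` writes `space.csv` / `space.geojson` with one row per target: raw and
proportional components, 95% CI bounds, Kish effective sample sizes,
convergence flag and the distance-weighted mean trait. All commands are
deterministic given `--seed`.

## Library example

```python
import geotwin as gt

field = gt.make_step_field(0.5, (0.55, 0.0, 0.45), (0.91, 0.0, 0.09))
pairs = gt.simulate_cohort(field, gt.CohortConfig(n_pairs=8000, seed=11))
std = gt.standardize_phenotype(pairs)
targets = gt.density_representative_targets(std, k=100, seed=11)
result = gt.run_space(std, targets, gt.ModelSpec("ACE"), gt.SpaceConfig(p=0.5))
result.to_csv("space.csv")
```

## Notes

- Variance components are parameterized as squared path coefficients, so
  they are non-negative by construction; fits at the `e² → 0` singular
  boundary are flagged `converged=False`.
- Weights are normalized to sum to the number of contributing pairs before
  fitting; point estimates are invariant to weight rescaling, and CIs are
  computed on the normalized weights.
- Confidence intervals are observed-information/delta-method intervals
  (`ci_method="observed_information"`, the only implemented method).
- Spatial weighting requires planar coordinates; records tagged with a
  geographic CRS are rejected until projected (`project_coordinates`).
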