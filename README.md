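# migsem

Phylogenetic piecewise structural equation modelling of annual-cycle bird
migration timing.

Given a table of annual-cycle tracking records (one row per tracked
individual or population, with breeding/non-breeding coordinates and the
four event dates that delimit the cycle), a species trait table (minimum
body masses per sex, taxonomy), and a phylogeny in Newick format, the
package:

1. validates the records (Northern-Hemisphere breeders, coordinate ranges,
   event order) and reports every rejected row with its reason;
2. derives period durations, great-circle migration distances, continuous
   day indices, body mass, and two-stage timing summaries (species means,
   then means and SDs across species, with period shares of the cycle and
   a paired t test of autumn vs spring duration);
3. builds the species-level phylogenetic variance–covariance/correlation
   matrix from the tree (pruned to the analysis species);
4. fits each equation of a hypothesized causal DAG as a linear mixed model
   with phylogenetic, species, paper-within-species, and year random
   intercepts and fully standardized (z-scored) variables, reporting
   standardized coefficients with 95% intervals, variance components,
   marginal/conditional R², VIFs, and convergence diagnostics;
5. decomposes standardized direct / indirect / total effects by
   significance-gated path tracing over the DAG, and evaluates the causal
   structure by d-separation (basis-set tests combined with Fisher's C);
6. ships a synthetic-data generator (Yule tree, traits with phylogenetic
   signal, DAG-structured records with known ground truth) so the whole
   pipeline is verifiable without any external data.

Two fitting backends share one interface: a fast profile-REML likelihood
backend (Wald intervals; default) and a Bayesian blocked Gibbs sampler
(4 chains × 10,000 iterations with 1,000 burn-in by default,
equal-tailed 95% credible intervals, split-R̂ convergence checks,
weakly-informative priors on the standardized scale).

## Command line

```sh
# generate a synthetic bundle (tracking.csv, traits.csv, tree.nwk, truth.json)
migsem simulate --seed 1 --n-species 30 --out demo/

# run the full pipeline from a YAML config
migsem run --config config.yaml

# stages individually
migsem fit --config config.yaml            # validate + derive + fit equations
migsem decompose --fits out/equations.json --out effects.csv
migsem report --artifacts out/
```

A minimal `config.yaml`:

```yaml
tracking: demo/tracking.csv
traits: demo/traits.csv
tree: demo/tree.nwk
out_dir: out
backend: reml        # or "mcmc" (requires seed)
seed: 1
include_sex: false
subset: {}           # e.g. {order: Order01} or {capture_site_class: breeding}
dag:
  add_edges: []      # e.g. [[FlightMode, BreedLat]]
  remove_edges: []
```

Artifacts written to `out_dir`: `derived.csv`, `timing_summary.csv`,
`species_means.csv`, `rejected_rows.csv`, `phylo_corr.csv`,
`equations.json` / `coefficients.csv`, `durations.json`, `effects.csv`,
`effect_table.csv` / `effect_table.txt`, `dsep_claims.csv`, `report.md`,
and `manifest.json` (versions, seed, config digest, per-stage timings).

## Library use

```python
from migsem.cycle_data import read_tracking_table, read_trait_table, derive_table
from migsem.phylo_cov import read_newick, prune_to_species, vcv_from_tree
from migsem.sem_engine import build_default_dag, assemble_matrix, fit_equation, FitSettings
from migsem.path_effects import decompose_effects, render_effect_table

records = read_tracking_table("tracking.csv").records
traits = read_trait_table("traits.csv")
derived = derive_table(records, traits)
phylo = vcv_from_tree(prune_to_species(read_newick("tree.nwk"),
                                       sorted(derived["species"].unique())))
dag = build_default_dag()
fits = {node: fit_equation(assemble_matrix(derived, node, dag=dag), phylo,
                           FitSettings(backend="reml"))
        for node in dag.endogenous}
print(render_effect_table(decompose_effects(dag, fits)).to_string(index=False))
```

## Conventions

- Day index: days since Jan 1 of the tracking year (Jan 1 = 1), continuing
  past 365 for events after Dec 31; linear means.
- The non-breeding period wraps from autumn arrival to the record's own
  departure date one year later, so the four durations always sum to the
  cycle length (365/366).
- Spring migration distance: last non-breeding site → breeding site;
  autumn: breeding site → first non-breeding site. Haversine on the IUGG
  mean-radius sphere (6371.0088 km).
- Body mass: sex-specific minimum mass, mean of the sexes when unknown;
  log-transformed before z-scoring.
- Southern-hemisphere non-breeding latitudes enter as absolute values.
- Significance: the 95% interval excludes zero; non-significant edges
  contribute nothing to path products and render as "-" in the effect
  table; rounding is half-away-from-zero with signed zeros ("-0.00").
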