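# pathprog

Network propagation turns a cancer patient's scattered somatic mutations into
a pathway-level portrait, and pathway *crosstalk* — the genes two pathways
share — turns out to carry much of the prognostic signal. `pathprog`
implements that idea end to end as a tested Python library:

1. **Propagation.** A patient's mutated genes seed a random walk with restart
   on a protein–protein interaction network, `F = αWF + (1−α)F₀` with `W` the
   column-normalized adjacency and `α = 0.7`. Per-gene significance comes
   from an empirical null of degree-preserving edge rewirings (150 by
   default): `p_g = (1 + #{null ≥ observed}) / (1 + n_null)`. The largest
   connected component of the significant genes — the giant cluster — is the
   patient's gene set.
2. **Oncogenic feature matrix.** K pathways define K pathway features plus
   K(K−1)/2 crosstalk features `C_ij = G_i ∩ G_j`. Each patient's giant
   cluster is scored against every feature by an upper-tail hypergeometric
   test over the network universe; entries are −log₁₀ p (54 pathways → 1485
   features).
3. **Critical feature selection.** A gradient-boosting classifier predicts
   vital status (stratified 8:2 split, randomized search on 5-fold CV
   Matthews correlation); features are ranked by gain importance and ranking
   prefixes are scanned for the two-group Ward clustering with the lowest
   log-rank p-value, subject to both groups holding ≥ 30% of the cohort. The
   poorer-surviving cluster is the short-term risk group; each selected
   feature is associated to a group by Welch's t-test.
4. **Network structure.** Selected crosstalk features form a
   pathway-interaction network, placed on a centralized / modular /
   distributed continuum via five metrics (power-law degree fit, normalized
   diameter, transitivity, closeness, edge-betweenness-community modularity)
   z-scored against size-matched random graphs.
5. **Cell-line screens.** Cell lines are mapped to risk groups by PCA-centroid
   proximity; knockout dependency scores (Student's t, p < 0.03) and z-scored
   drug IC50s (Welch's t) are screened for group-specific targets, with a
   cross-cancer repurposing filter.

A first-class synthetic-data module generates networks, pathway catalogues,
cohorts and cell-line panels with planted, parameterized prognostic structure,
so the whole pipeline is testable without any external downloads. See
`docs/methods.md` for the models, defaults and design choices.

## Worked example

```python
import pathprog as pp

spec = pp.SimulationSpec(rng_seed=1)   # 500 genes, 15 pathways, 300 patients,
                                       # 3 planted crosstalk features, HR = 8
network  = pp.generate_network(spec)
pathways = pp.generate_pathways(spec, network)
cohort, truth = pp.generate_cohort(spec, network, pathways)

matrix, catalogue = pp.build_feature_matrix(
    cohort, network, pathways, pp.PropagationConfig(n_null=50, rng_seed=1))
model   = pp.train_model(matrix, cohort.clinical["vital_status"],
                         split_seed=1, n_search=8)
ranking = pp.feature_importance(model)
cofs    = pp.select_cofs(ranking, matrix, cohort.clinical)
```

Running `python examples/select_critical_features.py` (exactly this analysis)
prints:

```
classifier: CV MCC = 0.103, held-out MCC = 0.169
16 critical features selected; log-rank p = 2.47e-22; groups: 119 short / 181 long
planted features recovered: ['P1-P2', 'P3-P4', 'P5-P6'] (3/3)
top associations: {'P10': 'long', 'P2': 'short', 'P12': 'long', 'P1': 'short', 'P14': 'long'}
```

The MCC is modest — vital status is a noisy label (carriers die at ~0.95 vs
~0.70 for non-carriers under the simulated censoring) — but the survival
stratification built from the importance ranking is decisive (log-rank
p ≈ 10⁻²²), both risk groups respect the 30% minimum size, and all three
planted crosstalk features are recovered among the 16 selected.

The other capabilities each have a narrative script under `examples/`:
`propagate_patient.py` (propagation + empirical null + giant cluster),
`feature_matrix.py` (cohort-scale matrix construction),
`network_structure.py` (structure metrics and continuum placement),
`cellline_screen.py` (panel assignment, dependency/drug screens,
repurposing).

## Command line

The same stages are exposed as a thin CLI for shell use:

```bash
pathprog --outdir run --seed 3 --n-null 50 full     # simulate -> screens
pathprog --config run.yaml featurize                # individual stages
```

Each stage writes plain TSV/JSON artifacts plus a `*.meta.json` sidecar with
the parameters, seeds and input checksums needed to reproduce it.

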