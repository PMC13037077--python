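"""Select critical (prognosis-stratifying) features from a feature matrix.

Trains the gradient-boosting vital-status classifier, ranks features by gain
importance, scans ranking prefixes for the two-group Ward clustering with the
lowest log-rank p-value (both groups >= 30% of the cohort), and reports which
planted features were recovered and how the risk groups separate.
"""

import pathprog as pp

spec = pp.SimulationSpec(rng_seed=1)  # 500 genes, 15 pathways, 300 patients
network = pp.generate_network(spec)
pathways = pp.generate_pathways(spec, network)
cohort, truth = pp.generate_cohort(spec, network, pathways)

matrix, _ = pp.build_feature_matrix(
    cohort, network, pathways, pp.PropagationConfig(n_null=50, rng_seed=1)
)
model = pp.train_model(matrix, cohort.clinical["vital_status"],
                       split_seed=1, n_search=8)
print(f"classifier: CV MCC = {model.cv_mcc:.3f}, "
      f"held-out MCC = {model.holdout_mcc:.3f}")

ranking = pp.feature_importance(model)
cofs = pp.select_cofs(ranking, matrix, cohort.clinical)

n_short = (cofs.grouping == "short").sum()
print(f"{len(cofs.feature_ids)} critical features selected; "
      f"log-rank p = {cofs.best_logrank_p:.2e}; "
      f"groups: {n_short} short / {len(cohort) - n_short} long")
hit = [f for f in truth.planted_features if f in cofs.feature_ids]
print(f"planted features recovered: {hit} ({len(hit)}/3)")
print("top associations:",
      {f: cofs.association[f] for f in cofs.feature_ids[:5]})
# 'short'-associated features score higher in the poor-prognosis group; the
# log-rank p is the survival separation of the two clustered patient groups.
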