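"""Propagate one patient's mutations over a gene network and extract the
significant giant cluster.

Builds a small synthetic interactome, seeds a random-walk-with-restart at a
handful of mutated genes, scores significance against 50 degree-preserving
rewirings, and prints the genes whose propagation scores cannot be explained
by degree alone.
"""

import numpy as np

import pathprog as pp

spec = pp.SimulationSpec(n_genes=200, rng_seed=0, planted_features=())
network = pp.generate_network(spec)

rng = np.random.default_rng(0)
mutated = {str(g) for g in rng.choice(sorted(network.nodes()), size=8, replace=False)}
print(f"patient mutations: {sorted(mutated)}")

seeds = pp.make_seeds(mutated, network, weighting="uniform")
config = pp.PropagationConfig(alpha=0.7, n_null=50)

observed = pp.propagate(seeds, network, config)
nulls = [
    pp.propagate(seeds, pp.rdpn(network, rng_seed=r), config)
    for r in range(config.n_null)
]
pvalues = pp.empirical_pvalues(observed, nulls)
significant = pp.significant_genes(pvalues, threshold=0.05)
cluster = pp.giant_cluster(significant, network)

top = sorted(observed, key=observed.get, reverse=True)[:5]
print("top propagation scores:",
      {g: round(float(observed[g]), 4) for g in top})
print(f"{len(significant)} genes significant at p<0.05; "
      f"giant cluster has {len(cluster)} genes")
# The giant cluster is the connected neighborhood the mutations converge on;
# it is the patient's gene set for pathway enrichment downstream.
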