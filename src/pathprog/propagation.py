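"""Random-walk-with-restart propagation on a gene network with a
degree-preserving null model.

The propagation solves the stationary equation

    F = alpha * W @ F + (1 - alpha) * F0

where ``W`` is the column-normalized adjacency matrix of the network and
``F0`` the normalized seed (restart) distribution built from a patient's
mutated genes. Column normalization conserves probability mass, so ``F``
sums to 1 whenever ``F0`` does.

Per-gene significance comes from an empirical null: the same seeds are
propagated on random degree-preserving networks (RDPNs, edge-swap rewirings
of the backbone) and each gene's p-value is the smoothed proportion of null
runs that scored at least as high as the observed run.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "PropagationConfig",
    "SeedVector",
    "PropagationResult",
    "make_seeds",
    "propagate",
    "run_propagation",
    "rdpn",
    "empirical_pvalues",
    "significant_genes",
    "giant_cluster",
    "column_normalized_adjacency",
    "propagate_matrix",
]

# dense closed-form solve below this size, power iteration above
_DENSE_SOLVE_MAX_NODES = 2000


@dataclass(frozen=True)
class PropagationConfig:
    """Propagation and null-model settings.

    alpha : restart-complement diffusion weight in (0, 1); 0.7 default.
    tol : L1 convergence tolerance of the power iteration.
    max_iter : iteration cap before a ConvergenceError.
    n_null : number of degree-preserving rewirings for the empirical null.
    swaps_per_edge : attempted double edge swaps per backbone edge.
    rng_seed : seed for the rewiring RNG stream.
    """

    alpha: float = 0.7
    tol: float = 1e-8
    max_iter: int = 10_000
    n_null: int = 150
    swaps_per_edge: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_null < 1:
            raise ValueError("n_null must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass(frozen=True)
class SeedVector:
    """Normalized restart distribution over network nodes."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        vals = np.fromiter(self.weights.values(), dtype=float, count=len(self.weights))
        if len(vals) == 0:
            raise ValueError("empty seed")
        if np.any(vals < 0):
            raise ValueError("seed weights must be nonnegative")
        total = vals.sum()
        if total <= 0:
            raise ValueError("empty seed")
        if abs(total - 1.0) > 1e-9:
            raise ValueError("seed weights must sum to 1")

    def as_array(self, nodes: list[str]) -> np.ndarray:
        arr = np.zeros(len(nodes))
        index = {g: i for i, g in enumerate(nodes)}
        for g, w in self.weights.items():
            if g not in index:
                raise ValueError(f"seed gene {g!r} not on the network")
            arr[index[g]] = w
        return arr


@dataclass(frozen=True)
class PropagationResult:
    """Per-gene steady-state scores, empirical p-values and the significant set."""

    scores: dict[str, float]
    pvalues: dict[str, float]
    significant: frozenset[str]


class ConvergenceError(RuntimeError):
    pass


def make_seeds(
    mutated_genes: set[str],
    network: nx.Graph,
    expression_column: dict[str, float] | None = None,
    weighting: str = "expression_abs_z",
) -> SeedVector:
    """Build the restart distribution from a patient's mutated genes.

    ``uniform`` places equal mass on every mutated gene present on the
    network; ``expression_abs_z`` weights each such gene by the absolute
    z-score of its expression across the cohort (``expression_column`` maps
    gene -> |z|), renormalized. Genes that are mutated but absent from the
    network are dropped (counted in the log); genes with zero |z| under
    expression weighting fall back to a small floor so a mutated gene is
    never silently erased by flat expression.
    """
    on_net = sorted(g for g in mutated_genes if g in network)
    if not on_net:
        raise ValueError("empty seed: no mutated gene is on the network")
    n_off = len(mutated_genes) - len(on_net)
    if n_off:
        import logging

        logging.getLogger(__name__).info(
            "dropped %d mutated gene(s) absent from the network", n_off
        )
    if weighting == "uniform":
        w = np.ones(len(on_net))
    elif weighting == "expression_abs_z":
        if expression_column is None:
            raise ValueError("expression_abs_z weighting requires expression_column")
        w = np.array([abs(expression_column.get(g, 0.0)) for g in on_net])
        if w.sum() == 0:
            w = np.ones(len(on_net))
        else:
            w = np.maximum(w, 1e-6 * w.max())
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    w = w / w.sum()
    return SeedVector(dict(zip(on_net, w)))


def column_normalized_adjacency(network: nx.Graph, nodes: list[str]) -> np.ndarray:
    """Dense adjacency with each nonzero column scaled to sum to 1."""
    a = nx.to_numpy_array(network, nodelist=nodes, dtype=float)
    colsum = a.sum(axis=0)
    colsum[colsum == 0] = 1.0
    return a / colsum


def propagate_matrix(
    f0: np.ndarray,
    w: np.ndarray,
    alpha: float,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    method: str = "auto",
) -> np.ndarray:
    """Solve F = alpha W F + (1-alpha) F0 for one or many seed columns.

    ``f0`` may be a vector or an (n_nodes, n_seeds) matrix. With
    ``method="auto"``, networks small enough for a dense factorization are
    solved in closed form and larger ones by power iteration with an L1
    stopping rule per column; ``"dense"`` / ``"iterative"`` force a path.
    """
    n = w.shape[0]
    if method not in ("auto", "dense", "iterative"):
        raise ValueError(f"unknown method {method!r}")
    if method == "dense" or (method == "auto" and n <= _DENSE_SOLVE_MAX_NODES):
        lhs = np.eye(n) - alpha * w
        return np.linalg.solve(lhs, (1.0 - alpha) * f0)
    f = f0.copy()
    for _ in range(max_iter):
        f_next = alpha * (w @ f) + (1.0 - alpha) * f0
        delta = np.abs(f_next - f).sum(axis=0).max()
        f = f_next
        if delta < tol:
            return f
    raise ConvergenceError(f"propagation did not converge; last L1 residual {delta:.3e}")


def propagate(
    seeds: SeedVector,
    network: nx.Graph,
    config: PropagationConfig = PropagationConfig(),
) -> dict[str, float]:
    """Propagate one seed vector over the network; returns per-gene scores."""
    nodes = sorted(network.nodes())
    w = column_normalized_adjacency(network, nodes)
    f0 = seeds.as_array(nodes)
    f = propagate_matrix(f0, w, config.alpha, config.tol, config.max_iter)
    return dict(zip(nodes, f))


def run_propagation(
    seeds: SeedVector,
    network: nx.Graph,
    config: PropagationConfig = PropagationConfig(),
    significance: float = 0.05,
) -> PropagationResult:
    """Propagate, score against the degree-preserving null, and threshold.

    Convenience wrapper bundling :func:`propagate` on the observed network,
    ``config.n_null`` rewired propagations, :func:`empirical_pvalues` and
    :func:`significant_genes` into one result object.
    """
    observed = propagate(seeds, network, config)
    nulls = [
        propagate(
            seeds,
            rdpn(network, rng_seed=config.rng_seed + 1 + r,
                 swaps_per_edge=config.swaps_per_edge),
            config,
        )
        for r in range(config.n_null)
    ]
    pvalues = empirical_pvalues(observed, nulls)
    return PropagationResult(
        scores=observed,
        pvalues=pvalues,
        significant=frozenset(significant_genes(pvalues, significance)),
    )


def rdpn(network: nx.Graph, rng_seed: int, swaps_per_edge: int = 10) -> nx.Graph:
    """Random degree-preserving network by repeated double edge swaps.

    Each accepted swap replaces edges (a,b), (c,d) with (a,d), (c,b),
    preserving every node's degree. Swaps that would introduce a self-loop
    or a multi-edge are rejected. The node set is preserved verbatim.
    """
    rng = random.Random(rng_seed)
    nodes = list(network.nodes())
    edges = [tuple(e) for e in network.edges()]
    edge_set = {frozenset(e) for e in edges}
    m = len(edges)
    if m < 2:
        return network.copy()
    target = swaps_per_edge * m
    done = 0
    attempts = 0
    max_attempts = 50 * target
    while done < target and attempts < max_attempts:
        attempts += 1
        i, j = rng.randrange(m), rng.randrange(m)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a,d) and (c,b)
        if a == d or c == b:
            continue
        e1, e2 = frozenset((a, d)), frozenset((c, b))
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(frozenset((a, b)))
        edge_set.discard(frozenset((c, d)))
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i] = (a, d)
        edges[j] = (c, b)
        done += 1
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(tuple(e) for e in edge_set)
    return g


def empirical_pvalues(
    observed: dict[str, float],
    null_scores: list[dict[str, float]],
) -> dict[str, float]:
    """Smoothed empirical p-value per gene.

    p_g = (1 + #{null runs with null_g >= observed_g}) / (1 + n_null),
    so p is never 0 and lies in [1/(n_null+1), 1]. The >= comparison and the
    pseudocount are deliberately conservative about ties.
    """
    n_null = len(null_scores)
    if n_null == 0:
        raise ValueError("n_null = 0: no null runs supplied")
    genes = list(observed)
    obs = np.array([observed[g] for g in genes])
    exceed = np.zeros(len(genes), dtype=int)
    for null in null_scores:
        nv = np.array([null.get(g, 0.0) for g in genes])
        exceed += nv >= obs
    p = (1.0 + exceed) / (1.0 + n_null)
    return dict(zip(genes, p))


def significant_genes(pvalues: dict[str, float], threshold: float = 0.05) -> set[str]:
    """Genes with p strictly below the threshold."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    return {g for g, p in pvalues.items() if p < threshold}


def giant_cluster(genes: set[str], network: nx.Graph) -> set[str]:
    """Largest connected component of the subgraph induced by ``genes``.

    Ties are broken toward the component containing the lexicographically
    smallest gene. Empty input yields the empty set.
    """
    if not genes:
        return set()
    missing = genes - set(network.nodes())
    if missing:
        raise ValueError(f"genes not on the network: {sorted(missing)[:3]}")
    sub = network.subgraph(genes)
    comps = sorted(nx.connected_components(sub), key=lambda c: (-len(c), min(c)))
    return set(comps[0])
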