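"""Pathway and pathway-crosstalk features, and the per-patient oncogenic
feature matrix.

Given K pathways the catalogue always contains K pathway features plus
K(K-1)/2 crosstalk ("link") features — one per unordered pathway pair, with
gene set the intersection of the two parent pathways. Pairs with an empty
intersection are kept in the catalogue, flagged, and produce all-zero matrix
columns, so the matrix shape depends only on K.

Each patient's significant giant cluster (from propagation) is scored
against every feature with an upper-tail hypergeometric test over the
network's gene universe; the matrix entry is -log10 of that p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import Cohort, PathwayCollection
from .propagation import (
    PropagationConfig,
    column_normalized_adjacency,
    empirical_pvalues,
    giant_cluster,
    make_seeds,
    propagate_matrix,
    rdpn,
    significant_genes,
)

logger = logging.getLogger(__name__)

__all__ = [
    "OncogenicFeature",
    "FeatureCatalogue",
    "enumerate_features",
    "enrich",
    "hypergeom_upper_tail",
    "build_feature_matrix",
    "geneset_enrichment_heatmap",
]


@dataclass(frozen=True)
class OncogenicFeature:
    """A single pathway ("Pi") or pathway-link ("Pi-Pj", i before j) feature."""

    feature_id: str
    genes: frozenset[str]
    is_link: bool

    @property
    def is_empty(self) -> bool:
        return len(self.genes) == 0


@dataclass(frozen=True)
class FeatureCatalogue:
    """Ordered feature list; column order of every feature matrix."""

    features: tuple[OncogenicFeature, ...]

    def __post_init__(self) -> None:
        ids = [f.feature_id for f in self.features]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate feature ids")

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    @property
    def ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    def by_id(self, feature_id: str) -> OncogenicFeature:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(feature_id)

    @property
    def n_links(self) -> int:
        return sum(f.is_link for f in self.features)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": [f.feature_id for f in self.features],
                "n_genes": [len(f.genes) for f in self.features],
                "is_link": [f.is_link for f in self.features],
                "is_empty": [f.is_empty for f in self.features],
                "genes": [";".join(sorted(f.genes)) for f in self.features],
            }
        )


def enumerate_features(pathways: PathwayCollection) -> FeatureCatalogue:
    """All K pathway features followed by all K(K-1)/2 link features.

    Link gene sets are the pairwise intersections; empty intersections are
    retained (flagged via ``is_empty``) so the catalogue size is a function
    of K alone.
    """
    k = len(pathways)
    if k < 2:
        raise ValueError("need at least 2 pathways")
    feats: list[OncogenicFeature] = [
        OncogenicFeature(pid, genes, is_link=False)
        for pid, _, genes in pathways
    ]
    ids = pathways.ids
    for i in range(k):
        for j in range(i + 1, k):
            inter = pathways.gene_sets[i] & pathways.gene_sets[j]
            feats.append(
                OncogenicFeature(f"{ids[i]}-{ids[j]}", frozenset(inter), is_link=True)
            )
    return FeatureCatalogue(tuple(feats))


def hypergeom_upper_tail(n_background: int, n_feature: int, n_cluster: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, n_background, n_feature, n_cluster))


def enrich(cluster: set[str], feature: OncogenicFeature, background: set[str]) -> float:
    """Upper-tail hypergeometric enrichment of a gene cluster in a feature.

    The feature's gene set is intersected with the background universe before
    testing; an effectively empty feature yields p = 1.
    """
    if not background:
        raise ValueError("empty background")
    if not cluster <= background:
        raise ValueError("cluster must be a subset of the background")
    eff = feature.genes & background
    if not eff:
        return 1.0
    k = len(cluster & eff)
    return hypergeom_upper_tail(len(background), len(eff), len(cluster), k)


def _enrich_row(
    cluster: set[str],
    catalogue: FeatureCatalogue,
    background: frozenset[str],
    eff_sizes: np.ndarray,
    feature_sets: list[frozenset[str]],
) -> np.ndarray:
    """-log10 enrichment p for one cluster against every catalogue feature."""
    n_bg = len(background)
    n_cl = len(cluster)
    ks = np.array([len(cluster & fs) for fs in feature_sets])
    p = np.ones(len(feature_sets))
    nonempty = eff_sizes > 0
    p[nonempty] = stats.hypergeom.sf(
        ks[nonempty] - 1, n_bg, eff_sizes[nonempty], n_cl
    )
    return -np.log10(np.clip(p, 1e-300, 1.0))


def build_feature_matrix(
    cohort: Cohort,
    network: nx.Graph,
    pathways: PathwayCollection,
    config: PropagationConfig = PropagationConfig(),
    weighting: str = "expression_abs_z",
    significance: float = 0.05,
) -> tuple[pd.DataFrame, FeatureCatalogue]:
    """Run propagation + null + giant cluster + enrichment for every patient.

    Returns the samples x features matrix of -log10 enrichment p-values and
    the catalogue defining its columns. The ``config.n_null`` rewired
    backbones are generated once and reused across patients: the null
    compares each gene's observed score with the same seeds diffused on
    degree-preserving rewirings, which does not depend on the patient order.

    Patients whose seeds cannot be formed (no mutated gene on the network)
    get an all-zero row and are listed in the log; an empty significant set
    or giant cluster likewise yields an all-zero row.
    """
    catalogue = enumerate_features(pathways)
    if 1.0 / (config.n_null + 1) >= significance:
        logger.warning(
            "n_null=%d cannot reach p < %g (floor %.3g): every row will be zero",
            config.n_null, significance, 1.0 / (config.n_null + 1),
        )
    nodes = sorted(network.nodes())
    background = frozenset(nodes)
    feature_sets = [f.genes & background for f in catalogue]
    eff_sizes = np.array([len(fs) for fs in feature_sets])

    # expression z-scores per gene across the cohort (for seed weighting)
    expr = cohort.expression
    if weighting == "expression_abs_z":
        mu = expr.mean(axis=1)
        sd = expr.std(axis=1).replace(0.0, 1.0)
        zmat = expr.sub(mu, axis=0).div(sd, axis=0)
    else:
        zmat = None

    samples = cohort.sample_ids
    seed_cols = np.zeros((len(nodes), len(samples)))
    node_index = {g: i for i, g in enumerate(nodes)}
    skipped: list[str] = []
    for si, s in enumerate(samples):
        try:
            col = zmat[s].to_dict() if zmat is not None else None
            sv = make_seeds(cohort.mutations[s], network, col, weighting)
        except ValueError:
            skipped.append(s)
            continue
        for g, wgt in sv.weights.items():
            seed_cols[node_index[g], si] = wgt
    if skipped:
        logger.warning(
            "%d patient(s) skipped (no mutated gene on the network): %s",
            len(skipped),
            skipped[:5],
        )

    w_obs = column_normalized_adjacency(network, nodes)
    f_obs = propagate_matrix(seed_cols, w_obs, config.alpha, config.tol, config.max_iter)

    null_f = []
    for r in range(config.n_null):
        g_null = rdpn(network, rng_seed=config.rng_seed + 1 + r,
                      swaps_per_edge=config.swaps_per_edge)
        w_null = column_normalized_adjacency(g_null, nodes)
        null_f.append(
            propagate_matrix(seed_cols, w_null, config.alpha, config.tol, config.max_iter)
        )

    rows = np.zeros((len(samples), len(catalogue)))
    for si, s in enumerate(samples):
        if s in skipped:
            continue
        exceed = np.zeros(len(nodes), dtype=int)
        obs = f_obs[:, si]
        for fn in null_f:
            exceed += fn[:, si] >= obs
        pvals = (1.0 + exceed) / (1.0 + config.n_null)
        sig = {nodes[i] for i in np.flatnonzero(pvals < significance)}
        cluster = giant_cluster(sig, network)
        if not cluster:
            continue
        rows[si] = _enrich_row(cluster, catalogue, background, eff_sizes, feature_sets)

    matrix = pd.DataFrame(rows, index=samples, columns=catalogue.ids)
    return matrix, catalogue


def geneset_enrichment_heatmap(
    label_genes: dict[str, set[str]],
    annotation_sets: dict[str, set[str]],
    background: set[str],
) -> pd.DataFrame:
    """Max-normalized -log10 hypergeometric enrichment of each labelled gene
    set (e.g. per-cancer COF genes) in each annotation set (e.g. hallmarks).

    Values lie in [0, 1]; an all-p=1 matrix is returned as zeros.
    """
    if not annotation_sets:
        raise ValueError("no annotation sets")
    if any(not s for s in annotation_sets.values()):
        raise ValueError("empty annotation set")
    labels = list(label_genes)
    anns = list(annotation_sets)
    mat = np.zeros((len(labels), len(anns)))
    n_bg = len(background)
    for i, lab in enumerate(labels):
        genes = label_genes[lab] & background
        for j, a in enumerate(anns):
            eff = annotation_sets[a] & background
            if not eff or not genes:
                continue
            k = len(genes & eff)
            p = hypergeom_upper_tail(n_bg, len(eff), len(genes), k)
            mat[i, j] = -np.log10(max(p, 1e-300))
    top = mat.max()
    if top > 0:
        mat = mat / top
    return pd.DataFrame(mat, index=labels, columns=anns)
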