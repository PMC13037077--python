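"""Synthetic networks, pathway catalogues, cohorts and cell-line panels with
planted, parameterized prognostic structure.

The generator mirrors the shapes of the real inputs (PPI edge lists, GMT
gene sets, mutation/expression/clinical TSVs, dependency and IC50 panels)
while planting a known signal: a subset of pathway-link features is made
prognostic by (i) concentrating the mutations of "active" patients inside
those features' gene neighborhoods, so propagation recovers them, and (ii)
multiplying those patients' event hazard by a configurable ratio. Every
generator is bit-reproducible given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import Cohort, PathwayCollection

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "generate_network",
    "generate_pathways",
    "generate_cohort",
    "generate_cellline_panel",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic dataset.

    Defaults describe a small but non-trivial cohort: a 500-gene scale-free
    interactome, 15 pathways of 20-40 genes with a modest shared-gene pool,
    300 patients with ~15 somatic mutations each, three planted prognostic
    pathway-link features with hazard ratio 8 between carriers and
    non-carriers, and 30% independent censoring.
    """

    n_genes: int = 500
    n_pathways: int = 15
    pathway_size_range: tuple[int, int] = (20, 40)
    overlap_fraction: float = 0.15
    planted_link_overlap: int = 8
    background_module_size: int = 6
    background_modules_per_patient: int = 2
    n_patients: int = 300
    mutations_per_patient: int = 20
    planted_features: tuple[str, ...] = ("P1-P2", "P3-P4", "P5-P6")
    hazard_ratio: float = 8.0
    baseline_median_days: float = 1000.0
    censoring_rate: float = 0.3
    expression_noise_sd: float = 1.0
    expression_effect: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if min(self.n_genes, self.n_pathways, self.n_patients,
               self.mutations_per_patient) <= 0:
            raise ValueError("all counts must be positive")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must be in [0, 1)")


@dataclass
class GroundTruth:
    """What was planted: per-patient carrier labels and the planted ids."""

    active: pd.Series  # sample -> bool
    planted_features: tuple[str, ...]
    planted_genes: dict[str, frozenset[str]] = field(default_factory=dict)


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def _planted_blocks(spec: SimulationSpec) -> list[list[str]]:
    """The dense gene modules backing the planted crosstalk features.

    Derived from the spec alone (not from a generated graph) so the network
    and pathway generators agree on them without sharing state.
    """
    if not spec.planted_features:
        return []
    rng = np.random.default_rng(spec.rng_seed + 7)
    perm = rng.permutation(spec.n_genes)
    size = spec.planted_link_overlap
    need = size * len(spec.planted_features)
    if need > spec.n_genes // 2:
        raise ValueError("infeasible overlap demand: planted blocks too large")
    return [
        sorted(_gene_name(i) for i in perm[b * size : (b + 1) * size])
        for b in range(len(spec.planted_features))
    ]


def _background_modules(spec: SimulationSpec) -> dict[int, list[str]]:
    """Per-parent-pathway "background" modules, hit by carriers and
    non-carriers alike.

    Each pathway that parents a planted link gets a private clique of
    ``background_module_size`` exclusive genes. Because every patient's
    mutations touch some of these modules, the parent pathway columns of the
    feature matrix are active across the whole cohort and only the shared
    crosstalk blocks separate carriers — the planted signal lives in the
    links, not the pathways.
    """
    if not spec.planted_features:
        return {}
    rng = np.random.default_rng(spec.rng_seed + 7)
    perm = rng.permutation(spec.n_genes)
    offset = spec.planted_link_overlap * len(spec.planted_features)
    parents = sorted(
        {idx for fid in spec.planted_features for idx in _parse_link(fid)}
    )
    size = spec.background_module_size
    if offset + size * len(parents) > spec.n_genes // 2:
        raise ValueError("infeasible overlap demand: modules exceed half the genome")
    out: dict[int, list[str]] = {}
    for b, p in enumerate(parents):
        lo = offset + b * size
        out[p] = sorted(_gene_name(i) for i in perm[lo : lo + size])
    return out


def generate_network(spec: SimulationSpec) -> nx.Graph:
    """Connected scale-free-ish interactome by preferential attachment.

    The genes backing each planted crosstalk feature are additionally wired
    into a clique, giving every planted feature a cohesive network module —
    the topological footprint the propagation step is meant to detect.
    """
    if spec.n_genes < 50:
        raise ValueError("n_genes must be >= 50")
    g = nx.barabasi_albert_graph(spec.n_genes, m=3, seed=spec.rng_seed)
    g = nx.relabel_nodes(g, {i: _gene_name(i) for i in g.nodes()})
    blocks = _planted_blocks(spec)
    for block in blocks:
        for a_i, a in enumerate(block):
            for b in block[a_i + 1 :]:
                g.add_edge(a, b)
    # bridge consecutive modules: inter-module crosstalk keeps a patient's
    # detected modules in one connected cluster
    for b1, b2 in zip(blocks, blocks[1:]):
        g.add_edge(b1[0], b2[0])
        g.add_edge(b1[-1], b2[-1])
    for module in _background_modules(spec).values():
        for a_i, a in enumerate(module):
            for b in module[a_i + 1 :]:
                g.add_edge(a, b)
    return g


def _parse_link(fid: str) -> tuple[int, int]:
    a, b = fid.split("-")
    return int(a[1:]) - 1, int(b[1:]) - 1


def generate_pathways(spec: SimulationSpec, network: nx.Graph) -> PathwayCollection:
    """Pathway gene sets with a controlled expected pairwise overlap.

    Every pathway draws ``c`` genes from a common pool of size ``2c`` (where
    ``c = 2 * overlap_fraction * mean_size``), making the expected shared
    count between any two pathways c^2 / 2c = overlap_fraction * mean_size;
    the rest of each pathway is exclusive. Pairs named in
    ``spec.planted_features`` additionally share ``planted_link_overlap``
    dedicated genes drawn from a connected network neighborhood, so those
    links are non-empty by construction and recoverable by propagation.
    """
    rng = np.random.default_rng(spec.rng_seed + 1)
    genes = sorted(network.nodes())
    lo, hi = spec.pathway_size_range
    if hi > spec.n_genes:
        raise ValueError("pathway sizes exceed the gene universe")
    k = spec.n_pathways
    sizes = rng.integers(lo, hi + 1, size=k)

    mean_size = sizes.mean()
    c = int(round(2 * spec.overlap_fraction * mean_size))
    pool_size = 2 * c

    planted_pairs = [_parse_link(f) for f in spec.planted_features]
    for i, j in planted_pairs:
        if not (0 <= i < k and 0 <= j < k and i < j):
            raise ValueError("planted feature references a missing pathway pair")

    planted_per_pathway: dict[int, set[str]] = {i: set() for i in range(k)}
    available = list(genes)
    rng.shuffle(available)

    # dedicated planted overlaps: one dense network module per planted pair
    taken: set[str] = set()
    blocks = _planted_blocks(spec)
    for (i, j), block in zip(planted_pairs, blocks):
        taken |= set(block)
        planted_per_pathway[i] |= set(block)
        planted_per_pathway[j] |= set(block)
    # private background modules: pinned exclusively to their parent pathway
    for p, module in _background_modules(spec).items():
        taken |= set(module)
        planted_per_pathway[p] |= set(module)

    free = [g for g in available if g not in taken]
    pool = free[:pool_size]
    free = free[pool_size:]

    # feasibility: exclusive genes needed in the worst case
    sets: list[frozenset[str]] = []
    cursor = 0
    for idx in range(k):
        planted = planted_per_pathway[idx]
        draw_c = min(c, max(int(sizes[idx]) - len(planted), 0))
        shared = (
            list(rng.choice(pool, size=draw_c, replace=False)) if draw_c and pool else []
        )
        need = int(sizes[idx]) - len(planted) - len(shared)
        if need < 0:
            need = 0
        if cursor + need > len(free):
            raise ValueError("infeasible overlap demand: gene universe exhausted")
        exclusive = free[cursor : cursor + need]
        cursor += need
        sets.append(frozenset(planted) | frozenset(shared) | frozenset(exclusive))

    ids = tuple(f"P{i + 1}" for i in range(k))
    names = tuple(f"synthetic pathway {i + 1}" for i in range(k))
    return PathwayCollection(ids, names, tuple(sets))


def _planted_gene_sets(
    spec: SimulationSpec, pathways: PathwayCollection
) -> dict[str, frozenset[str]]:
    out = {}
    for fid in spec.planted_features:
        i, j = _parse_link(fid)
        out[fid] = pathways.gene_sets[i] & pathways.gene_sets[j]
        if not out[fid]:
            raise ValueError(f"planted feature {fid} is empty in the catalogue")
    return out


def generate_cohort(
    spec: SimulationSpec,
    network: nx.Graph,
    pathways: PathwayCollection,
) -> tuple[Cohort, GroundTruth]:
    """Cohort with a planted carrier subgroup.

    Half the patients (in expectation) are carriers ("active"): most of their
    mutations fall inside the planted links' gene neighborhoods (the shared
    genes plus their 1-hop network neighbors) and their event hazard is
    ``hazard_ratio`` times the baseline exponential hazard (median
    ``baseline_median_days`` for non-carriers). Expression is Gaussian noise
    with a mean shift of ``expression_effect`` on planted genes in carriers.
    Censoring is independent exponential, calibrated so the expected censored
    fraction equals ``censoring_rate`` in each arm.
    """
    rng = np.random.default_rng(spec.rng_seed + 2)
    genes = sorted(network.nodes())
    planted_sets = _planted_gene_sets(spec, pathways)

    rings: dict[str, list[str]] = {}
    for fid, gs in planted_sets.items():
        ring = set()
        for gname in gs:
            ring |= set(network.neighbors(gname))
        rings[fid] = sorted(ring - gs)
    bg_modules = list(_background_modules(spec).values())

    samples = [f"S{i:04d}" for i in range(spec.n_patients)]
    active = rng.random(spec.n_patients) < 0.5

    mutations: dict[str, set[str]] = {}
    n_mut = spec.mutations_per_patient
    n_per_module = max(2, int(round(2 * spec.background_module_size / 3)))
    for idx, s in enumerate(samples):
        picks: set[str] = set()
        if active[idx]:
            n_planted = max(1, int(round(0.8 * n_mut)))
            for fid in spec.planted_features:
                core = sorted(planted_sets[fid])
                take = max(2, n_planted // len(spec.planted_features))
                # seed mostly the shared genes themselves: the planted module
                # is a cohesive subgraph, so co-seeded members amplify each
                # other under propagation; one 1-hop neighbor mimics
                # mutations adjacent to the crosstalk
                n_core = min(take, len(core))
                picks |= set(rng.choice(core, size=n_core, replace=False))
                ring = rings[fid]
                if ring and rng.random() < 0.5:
                    picks.add(str(rng.choice(ring)))
            n_modules = min(1, len(bg_modules))
        else:
            n_modules = min(spec.background_modules_per_patient, len(bg_modules))
        # background pathway activation, carrier status notwithstanding
        if n_modules:
            for mi in rng.choice(len(bg_modules), size=n_modules, replace=False):
                module = bg_modules[mi]
                picks |= set(
                    rng.choice(module, size=min(n_per_module, len(module)),
                               replace=False)
                )
        n_bg = max(n_mut - len(picks), 0)
        picks |= set(rng.choice(genes, size=n_bg, replace=False))
        mutations[s] = picks

    expr = rng.normal(0.0, spec.expression_noise_sd, size=(len(genes), len(samples)))
    expression = pd.DataFrame(expr, index=genes, columns=samples)
    planted_all = sorted(set().union(*planted_sets.values()))
    expression.loc[planted_all, np.array(samples)[active]] += spec.expression_effect

    lam0 = np.log(2.0) / spec.baseline_median_days
    lam = np.where(active, lam0 * spec.hazard_ratio, lam0)
    t_event = rng.exponential(1.0 / lam)
    if spec.censoring_rate > 0:
        # one censoring process for the whole cohort (loss to follow-up does
        # not know who carries the signal), calibrated so the non-carrier arm
        # is censored at exactly `censoring_rate`; carriers, dying faster,
        # are censored less often
        lam_c = lam0 * spec.censoring_rate / (1.0 - spec.censoring_rate)
        t_cens = rng.exponential(1.0 / lam_c, size=spec.n_patients)
    else:
        t_cens = np.full(spec.n_patients, np.inf)
    time = np.maximum(np.minimum(t_event, t_cens), 0.5)
    status = (t_event <= t_cens).astype(int)

    clinical = pd.DataFrame(
        {"vital_status": status, "time_days": time}, index=pd.Index(samples, name="sample_id")
    )
    cohort = Cohort(mutations=mutations, expression=expression, clinical=clinical)
    truth = GroundTruth(
        active=pd.Series(active, index=samples, name="active"),
        planted_features=spec.planted_features,
        planted_genes=planted_sets,
    )
    return cohort, truth


def generate_cellline_panel(
    patient_matrix: pd.DataFrame,
    grouping: pd.Series,
    cof_ids: list[str],
    n_lines_per_group: int = 8,
    n_dep_genes: int = 200,
    planted_dep_genes: int = 5,
    n_compounds: int = 40,
    planted_compounds: int = 2,
    noise_sd: float = 0.5,
    rng_seed: int = 0,
) -> dict[str, object]:
    """Cell-line panel mirroring the patient risk groups.

    Each synthetic line's COF profile is the mean profile of one patient risk
    group plus Gaussian noise, so centroid assignment can recover its group.
    The dependency matrix plants ``planted_dep_genes`` genes essential only in
    short-group lines (strongly negative scores); the IC50 z-matrix plants
    ``planted_compounds`` compounds more effective in the short group. Returns
    a dict with keys ``cof_matrix``, ``dependency``, ``ic50_z``,
    ``true_groups``, ``planted_dep_genes``, ``planted_compounds``.
    """
    rng = np.random.default_rng(rng_seed)
    cols = [c for c in cof_ids if c in patient_matrix.columns]
    prof = {
        g: patient_matrix.loc[(grouping == g).to_numpy(), cols].mean(axis=0).to_numpy()
        for g in ("short", "long")
    }
    lines, rows, truth = [], [], []
    for g in ("short", "long"):
        for i in range(n_lines_per_group):
            lines.append(f"CL_{g}_{i:02d}")
            rows.append(prof[g] + rng.normal(0, noise_sd, size=len(cols)))
            truth.append(g)
    cof_matrix = pd.DataFrame(rows, index=lines, columns=cols)
    true_groups = pd.Series(truth, index=lines, name="group")

    dep_gene_names = [f"D{i:04d}" for i in range(n_dep_genes)]
    dep = rng.normal(0.0, 0.3, size=(n_dep_genes, len(lines)))
    short_cols = np.array([g == "short" for g in truth])
    for gi in range(planted_dep_genes):
        dep[gi, short_cols] = rng.normal(-1.0, 0.2, size=short_cols.sum())
        dep[gi, ~short_cols] = rng.normal(0.1, 0.2, size=(~short_cols).sum())
    dependency = pd.DataFrame(dep, index=dep_gene_names, columns=lines)

    comp_names = [f"CPD{i:03d}" for i in range(n_compounds)]
    ic50 = rng.normal(0.0, 1.0, size=(n_compounds, len(lines)))
    for ci in range(planted_compounds):
        ic50[ci, short_cols] -= 1.5
    ic50_z = pd.DataFrame(ic50, index=comp_names, columns=lines)

    return {
        "cof_matrix": cof_matrix,
        "dependency": dependency,
        "ic50_z": ic50_z,
        "true_groups": true_groups,
        "planted_dep_genes": dep_gene_names[:planted_dep_genes],
        "planted_compounds": comp_names[:planted_compounds],
    }
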