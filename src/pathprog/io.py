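"""Readers, writers and cohort plumbing.

File formats are deliberately plain: GMT for gene sets, headered TSV for
everything else (edge lists, mutation calls, expression matrices, clinical
tables). Gene identifiers are opaque strings; any symbol mapping is the
caller's job.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayCollection",
    "Cohort",
    "CohortReport",
    "read_gene_sets",
    "write_gene_sets",
    "read_edge_list",
    "write_edge_list",
    "normalize_edges",
    "largest_component",
    "build_consensus_network",
    "read_cohort",
    "write_cohort",
    "filter_cohort",
]


class GmtParseError(ValueError):
    """Raised when a GMT file violates the three-column minimum."""


@dataclass(frozen=True)
class PathwayCollection:
    """An ordered catalogue of gene sets.

    Order is load-bearing: downstream feature enumeration assigns feature ids
    by position, so two collections with the same sets in different order are
    different catalogues.
    """

    ids: tuple[str, ...]
    names: tuple[str, ...]
    gene_sets: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("duplicate pathway ids")
        if not all(self.gene_sets):
            raise ValueError("empty pathway gene set")
        if not (len(self.ids) == len(self.names) == len(self.gene_sets)):
            raise ValueError("ids, names and gene_sets must align")

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(zip(self.ids, self.names, self.gene_sets))

    def genes(self) -> frozenset[str]:
        """Union of all member genes."""
        out: set[str] = set()
        for gs in self.gene_sets:
            out |= gs
        return frozenset(out)


@dataclass
class Cohort:
    """Per-patient mutations, expression and clinical follow-up.

    ``mutations`` maps sample id -> set of mutated genes; ``expression`` is a
    genes x samples float frame; ``clinical`` is indexed by sample id with
    columns ``vital_status`` (0 alive / 1 deceased) and ``time_days`` (> 0).
    """

    mutations: dict[str, set[str]]
    expression: pd.DataFrame
    clinical: pd.DataFrame

    def __post_init__(self) -> None:
        samples = list(self.clinical.index)
        if len(samples) != len(set(samples)):
            raise ValueError("duplicate sample ids in clinical table")
        missing_mut = [s for s in samples if s not in self.mutations]
        missing_exp = [s for s in samples if s not in self.expression.columns]
        if missing_mut or missing_exp:
            raise ValueError(
                f"samples missing mutation ({missing_mut[:3]}) or "
                f"expression ({missing_exp[:3]}) entries"
            )
        times = self.clinical["time_days"].to_numpy(dtype=float)
        if np.any(times <= 0) or np.any(~np.isfinite(times)):
            raise ValueError("survival times must be strictly positive and finite")
        status = self.clinical["vital_status"].to_numpy()
        if not np.isin(status, (0, 1)).all():
            raise ValueError("vital_status must be binary (0 alive, 1 deceased)")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.clinical.index)

    def __len__(self) -> int:
        return len(self.clinical)


@dataclass(frozen=True)
class CohortReport:
    """Eligibility report for a cohort against the study inclusion filters."""

    n: int
    deceased_fraction: float
    median_followup_days: float
    passed: bool
    reasons: tuple[str, ...] = field(default=())


def read_gene_sets(path: str | Path) -> PathwayCollection:
    """Parse a GMT file (id, description, genes...) into a collection.

    Genes are deduplicated within a line (first occurrence kept); line order
    is preserved.
    """
    ids: list[str] = []
    names: list[str] = []
    sets: list[frozenset[str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(parts)}"
                )
            pid, name, *genes = parts
            genes = [g for g in genes if g]
            seen: dict[str, None] = dict.fromkeys(genes)
            if pid in ids:
                raise GmtParseError(f"{path}: line {lineno}: duplicate pathway id {pid!r}")
            ids.append(pid)
            names.append(name)
            sets.append(frozenset(seen))
    return PathwayCollection(tuple(ids), tuple(names), tuple(sets))


def write_gene_sets(pathways: PathwayCollection, path: str | Path) -> None:
    """Write a collection back to GMT (genes sorted for byte stability)."""
    with open(path, "w") as fh:
        for pid, name, genes in pathways:
            fh.write("\t".join([pid, name, *sorted(genes)]) + "\n")


def normalize_edges(edges: Iterable[tuple[str, str]]) -> set[tuple[str, str]]:
    """Canonicalize to lexicographically sorted endpoint pairs, dropping
    self-loops (count logged) and duplicates."""
    out: set[tuple[str, str]] = set()
    n_loops = 0
    for a, b in edges:
        if a == b:
            n_loops += 1
            continue
        out.add((a, b) if a < b else (b, a))
    if n_loops:
        logger.info("dropped %d self-loop edge(s)", n_loops)
    return out


def read_edge_list(path: str | Path) -> set[tuple[str, str]]:
    """Read a two(+)-column TSV edge list; header row optional if it is
    literally 'gene_a\\tgene_b'."""
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if parts[0] == "gene_a" and parts[1] == "gene_b":
                continue
            edges.append((parts[0], parts[1]))
    return normalize_edges(edges)


def write_edge_list(network: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in network.edges()):
            fh.write(f"{a}\t{b}\n")


def largest_component(network: nx.Graph) -> nx.Graph:
    """Largest connected component; ties broken by the lexicographically
    smallest member node."""
    if network.number_of_nodes() == 0:
        return network.copy()
    comps = list(nx.connected_components(network))
    comps.sort(key=lambda c: (-len(c), min(c)))
    return network.subgraph(comps[0]).copy()


def build_consensus_network(
    edge_lists: Sequence[Iterable[tuple[str, str]]],
    min_sources: int = 2,
) -> nx.Graph:
    """Keep edges found in at least ``min_sources`` input lists, then return
    the largest connected component.

    Each edge of the result carries a ``sources`` attribute (the number of
    inputs that contained it).
    """
    if min_sources < 1:
        raise ValueError("min_sources must be >= 1")
    counts: dict[tuple[str, str], int] = {}
    for lst in edge_lists:
        for e in normalize_edges(lst):
            counts[e] = counts.get(e, 0) + 1
    kept = {e: c for e, c in counts.items() if c >= min_sources}
    if not kept:
        raise ValueError("no consensus edges")
    g = nx.Graph()
    # sorted: node/edge insertion order must not depend on hash order
    for (a, b) in sorted(kept):
        g.add_edge(a, b, sources=kept[(a, b)])
    return largest_component(g)


def read_cohort(
    mutations_path: str | Path,
    expression_path: str | Path,
    clinical_path: str | Path,
) -> Cohort:
    """Assemble a cohort from the three TSV inputs, intersected on common
    samples (dropped samples are logged)."""
    mut = pd.read_csv(mutations_path, sep="\t", dtype=str)
    expr = pd.read_csv(expression_path, sep="\t", index_col=0)
    clin = pd.read_csv(clinical_path, sep="\t", index_col=0)

    mut_samples = set(mut["sample_id"])
    common = [
        s
        for s in clin.index
        if s in mut_samples and s in expr.columns
    ]
    dropped = (set(clin.index) | mut_samples | set(expr.columns)) - set(common)
    if dropped:
        logger.warning("dropped %d sample(s) absent from some input", len(dropped))
    if not common:
        raise ValueError("no samples shared by mutation, expression and clinical inputs")

    mutations = {s: set() for s in common}
    for s, g in zip(mut["sample_id"], mut["gene"]):
        if s in mutations:
            mutations[s].add(g)
    clinical = clin.loc[common, ["vital_status", "time_days"]].astype(
        {"vital_status": int, "time_days": float}
    )
    return Cohort(mutations=mutations, expression=expr[common], clinical=clinical)


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict[str, Path]:
    """Write a cohort in the three standard TSVs; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mutations": outdir / "mutations.tsv",
        "expression": outdir / "expression.tsv",
        "clinical": outdir / "clinical.tsv",
    }
    rows = [
        {"sample_id": s, "gene": g}
        for s in cohort.sample_ids
        for g in sorted(cohort.mutations[s])
    ]
    pd.DataFrame(rows, columns=["sample_id", "gene"]).to_csv(
        paths["mutations"], sep="\t", index=False
    )
    cohort.expression.to_csv(paths["expression"], sep="\t", float_format="%.6g")
    cohort.clinical.to_csv(paths["clinical"], sep="\t", index_label="sample_id")
    return paths


def filter_cohort(
    cohort: Cohort,
    min_n: int = 200,
    ratio_bounds: tuple[float, float] = (0.15, 0.85),
    min_median_followup_days: float = 365.25,
) -> CohortReport:
    """Check the cohort against the study eligibility filters.

    The three statistics are always computed and returned; ``passed`` is the
    conjunction. Median follow-up is taken over censored (alive) patients; if
    nobody is censored it is reported as 0 and fails the follow-up filter
    only if the threshold is positive.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    n = len(cohort)
    status = cohort.clinical["vital_status"].to_numpy()
    frac_dead = float(status.mean())
    alive_times = cohort.clinical.loc[status == 0, "time_days"].to_numpy(dtype=float)
    median_fu = float(np.median(alive_times)) if alive_times.size else 0.0

    reasons: list[str] = []
    if n < min_n:
        reasons.append(f"n={n} < {min_n}")
    lo, hi = ratio_bounds
    if not (lo <= frac_dead <= hi):
        reasons.append(f"deceased fraction {frac_dead:.3f} outside [{lo}, {hi}]")
    if median_fu <= min_median_followup_days:
        reasons.append(
            f"median follow-up {median_fu:.0f} d <= {min_median_followup_days:.0f} d"
        )
    return CohortReport(
        n=n,
        deceased_fraction=frac_dead,
        median_followup_days=median_fu,
        passed=not reasons,
        reasons=tuple(reasons),
    )
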