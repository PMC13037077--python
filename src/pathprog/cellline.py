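"""Projecting cell lines onto patient risk groups and screening perturbation
panels for group-specific vulnerabilities.

Cell-line feature rows (restricted to the patient-derived COF columns) are
embedded together with the patient rows by PCA; each line is assigned to the
risk group whose patient centroid is nearer in the 2-D embedding. Gene
knockout dependency scores and z-scored drug IC50s are then compared between
the short- and long-term line groups to nominate group-specific targets and
cross-cancer repurposing candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .cof import LONG, SHORT
from .features import FeatureCatalogue, enrich

logger = logging.getLogger(__name__)

__all__ = [
    "PanelAssignment",
    "project_and_assign",
    "differential_dependency",
    "drug_response_diff",
    "repurposing_screen",
    "hit_crosstalk_enrichment",
]

AMBIGUOUS = "ambiguous"


@dataclass
class PanelAssignment:
    """Risk-group assignment of each cell line by centroid proximity."""

    groups: pd.Series  # cell line -> short / long / ambiguous
    coordinates: pd.DataFrame  # all rows (patients + lines) x 2 PCs
    centroids: dict[str, np.ndarray]

    def lines_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


def project_and_assign(
    patient_cof_matrix: pd.DataFrame,
    cellline_cof_matrix: pd.DataFrame,
    grouping: pd.Series,
) -> PanelAssignment:
    """PCA-embed patients and cell lines on the shared COF columns and assign
    each line to the nearest patient risk-group centroid.

    The PCA (2 components) is fit on the union of patient and cell-line rows;
    centroids are the per-group means of the *patient* coordinates only.
    Exact ties in centroid distance are labelled ambiguous.
    """
    cols = [c for c in patient_cof_matrix.columns if c in cellline_cof_matrix.columns]
    if len(cols) < 2:
        raise ValueError("need at least 2 shared COF columns for a 2-D embedding")
    pat = patient_cof_matrix[cols]
    cl = cellline_cof_matrix[cols]
    combined = pd.concat([pat, cl], axis=0)
    pca = PCA(n_components=2, random_state=0)
    coords = pd.DataFrame(
        pca.fit_transform(combined.to_numpy(dtype=float)),
        index=combined.index,
        columns=["PC1", "PC2"],
    )
    pat_coords = coords.loc[pat.index]
    centroids = {
        g: pat_coords[(grouping.loc[pat.index] == g).to_numpy()].mean(axis=0).to_numpy()
        for g in (SHORT, LONG)
    }
    assignments = {}
    for line in cl.index:
        x = coords.loc[line].to_numpy()
        d_short = float(np.linalg.norm(x - centroids[SHORT]))
        d_long = float(np.linalg.norm(x - centroids[LONG]))
        if np.isclose(d_short, d_long, rtol=1e-9, atol=1e-12):
            assignments[line] = AMBIGUOUS
        else:
            assignments[line] = SHORT if d_short < d_long else LONG
    return PanelAssignment(
        groups=pd.Series(assignments, name="group"),
        coordinates=coords,
        centroids=centroids,
    )


def _group_columns(matrix: pd.DataFrame, assignment: PanelAssignment):
    short_lines = [l for l in assignment.lines_in(SHORT) if l in matrix.columns]
    long_lines = [l for l in assignment.lines_in(LONG) if l in matrix.columns]
    return short_lines, long_lines


def differential_dependency(
    dep_matrix: pd.DataFrame,
    assignment: PanelAssignment,
    alpha: float = 0.03,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Student's t-test of knockout dependency per gene between risk groups.

    Genes with p < alpha are selected and categorized by the sign of the
    group mean dependency: below zero in both groups -> "Short & Long";
    below zero only in the short (resp. long) group -> "Short only" /
    "Long only"; otherwise "neither". Rows: gene; columns: means, t, p,
    selected, category.
    """
    short_lines, long_lines = _group_columns(dep_matrix, assignment)
    if len(short_lines) < 3 or len(long_lines) < 3:
        raise ValueError("need >= 3 cell lines per risk group")
    rows = dep_matrix.index if genes is None else [g for g in genes if g in dep_matrix.index]
    a = dep_matrix.loc[rows, short_lines].to_numpy(dtype=float)
    b = dep_matrix.loc[rows, long_lines].to_numpy(dtype=float)
    # zero-variance guard: a vanishing pooled variance makes t undefined;
    # those genes get p = 1 unless the means differ with exactly constant
    # groups, where the difference is taken at face value (p = 0)
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    mean_s, mean_l = a.mean(axis=1), b.mean(axis=1)
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate & (mean_s == mean_l), 1.0, p)
    p = np.where(~np.isfinite(p), 0.0, p)
    selected = p < alpha
    category = np.full(len(rows), "neither", dtype=object)
    category[(mean_s < 0) & (mean_l < 0)] = "Short & Long"
    category[(mean_s < 0) & (mean_l >= 0)] = "Short only"
    category[(mean_s >= 0) & (mean_l < 0)] = "Long only"
    return pd.DataFrame(
        {
            "mean_short": mean_s,
            "mean_long": mean_l,
            "t": t,
            "p": p,
            "selected": selected,
            "category": category,
        },
        index=pd.Index(rows, name="gene"),
    )


def drug_response_diff(
    ic50_z: pd.DataFrame,
    assignment: PanelAssignment,
    alpha: float = 0.05,
    min_lines: int = 3,
) -> pd.DataFrame:
    """Welch t-test of z-scored IC50 per compound between risk groups.

    A lower mean z means the group is more sensitive, so a significant
    compound is labelled effective against the group with the lower mean.
    Compounds measured in fewer than ``min_lines`` lines per group are
    skipped (logged).
    """
    short_lines, long_lines = _group_columns(ic50_z, assignment)
    records = []
    skipped = 0
    for comp in ic50_z.index:
        a = ic50_z.loc[comp, short_lines].dropna().to_numpy(dtype=float)
        b = ic50_z.loc[comp, long_lines].dropna().to_numpy(dtype=float)
        if len(a) < min_lines or len(b) < min_lines:
            skipped += 1
            continue
        t, p = stats.ttest_ind(a, b, equal_var=False)
        if not np.isfinite(p):
            p = 1.0
        effective = SHORT if a.mean() < b.mean() else LONG
        records.append(
            {
                "compound": comp,
                "mean_short": a.mean(),
                "mean_long": b.mean(),
                "t": t,
                "p": p,
                "significant": p < alpha,
                "effective_against": effective if p < alpha else "none",
            }
        )
    if skipped:
        logger.info("skipped %d compound(s) with < %d lines per group", skipped, min_lines)
    return pd.DataFrame.from_records(records).set_index("compound") if records else (
        pd.DataFrame(
            columns=["mean_short", "mean_long", "t", "p", "significant",
                     "effective_against"]
        )
    )


def repurposing_screen(
    results_by_cancer: dict[str, pd.DataFrame],
    approved_map: dict[str, set[str]],
) -> pd.DataFrame:
    """Cross-cancer repurposing candidates.

    For each screened cancer type, candidates are compounds significantly
    more effective against its short-term risk group that are approved for at
    least one *other* cancer type (and not for the screened type itself).
    Rows carry the screened cancer, compound, p, and origin cancer types.
    """
    records = []
    for cancer, table in results_by_cancer.items():
        own = approved_map.get(cancer, set())
        if table.empty:
            continue
        hits = table[(table["significant"]) & (table["effective_against"] == SHORT)]
        for comp, row in hits.iterrows():
            origins = sorted(
                c for c, drugs in approved_map.items() if comp in drugs and c != cancer
            )
            if comp in own or not origins:
                continue
            records.append(
                {
                    "cancer_type": cancer,
                    "compound": comp,
                    "p": row["p"],
                    "origin_cancer_types": ";".join(origins),
                }
            )
    return pd.DataFrame.from_records(
        records, columns=["cancer_type", "compound", "p", "origin_cancer_types"]
    )


def hit_crosstalk_enrichment(
    hit_genes: set[str],
    catalogue: FeatureCatalogue,
    background: set[str],
    cof_ids: set[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of screen hits in every catalogue feature;
    features with p < alpha are returned, flagged when they are COFs."""
    if not hit_genes:
        return pd.DataFrame(columns=["feature_id", "p", "is_cof"])
    records = []
    for feat in catalogue:
        p = enrich(hit_genes & background, feat, background)
        if p < alpha:
            records.append(
                {
                    "feature_id": feat.feature_id,
                    "p": p,
                    "is_cof": bool(cof_ids and feat.feature_id in cof_ids),
                }
            )
    out = pd.DataFrame.from_records(records, columns=["feature_id", "p", "is_cof"])
    return out.sort_values("p").reset_index(drop=True)
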