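"""Critical oncogenic feature (COF) selection.

A gradient-boosting classifier is trained to predict vital status from the
oncogenic feature matrix; its gain-based importances rank the features. The
ranked features are then added one at a time, each prefix is clustered into
two patient groups (Ward linkage, Euclidean distance) and the prefix whose
grouping gives the lowest log-rank p-value — with both groups at least 30%
of the cohort — defines the COF set. The poorer-surviving group is labelled
short-term risk; each selected feature is finally associated with the group
in which it scores higher (Welch t-test, p <= 0.05) or left unassigned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import RandomizedSearchCV, train_test_split
from sklearn.metrics import make_scorer

__all__ = [
    "TrainedModel",
    "ImportanceRanking",
    "COFSet",
    "train_model",
    "feature_importance",
    "select_cofs",
    "assign_risk_labels",
    "classify_cofs",
    "mcc",
]

SHORT = "short"
LONG = "long"
UNASSIGNED = "unassigned"


def mcc(predicted, truth) -> float:
    """Matthews correlation coefficient from two binary label vectors.

    Returns 0.0 when any confusion-matrix margin is empty (the coefficient is
    undefined there; 0 is the no-information convention).
    """
    pred = np.asarray(predicted).astype(int)
    true = np.asarray(truth).astype(int)
    if pred.shape != true.shape:
        raise ValueError("predicted and truth must have the same length")
    tp = int(np.sum((pred == 1) & (true == 1)))
    tn = int(np.sum((pred == 0) & (true == 0)))
    fp = int(np.sum((pred == 1) & (true == 0)))
    fn = int(np.sum((pred == 0) & (true == 1)))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


_SEARCH_SPACE = {
    "n_estimators": [50, 100, 200],
    "max_depth": [2, 3, 4],
    "learning_rate": [0.05, 0.1, 0.2],
    "subsample": [0.7, 0.85, 1.0],
    "min_samples_leaf": [1, 5, 10],
}


@dataclass
class TrainedModel:
    """Fitted classifier with its cross-validated and held-out MCC."""

    estimator: GradientBoostingClassifier
    cv_mcc: float
    holdout_mcc: float
    split_seed: int
    hyperparameters: dict = field(default_factory=dict)
    feature_ids: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class ImportanceRanking:
    """Features ordered by descending importance; ties broken by feature id."""

    entries: tuple[tuple[str, float], ...]

    @property
    def feature_ids(self) -> list[str]:
        return [f for f, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class COFSet:
    """The selected importance-prefix, the stratification it induces, and the
    per-feature risk-group association."""

    feature_ids: list[str]
    best_logrank_p: float
    grouping: pd.Series  # sample -> "short" / "long"
    association: dict[str, str]
    importance: dict[str, float] = field(default_factory=dict)


def train_model(
    matrix: pd.DataFrame,
    labels: pd.Series,
    split_seed: int = 0,
    n_search: int = 20,
    cv_folds: int = 5,
) -> TrainedModel:
    """Train the vital-status classifier on the feature matrix.

    Stratified 80/20 train/test split; hyperparameters drawn by randomized
    search maximizing mean 5-fold CV MCC on the training portion; held-out
    MCC reported from the untouched 20%.
    """
    y = labels.loc[matrix.index].to_numpy().astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    x = matrix.to_numpy(dtype=float)
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=0.2, stratify=y, random_state=split_seed
    )
    search = RandomizedSearchCV(
        GradientBoostingClassifier(random_state=split_seed),
        _SEARCH_SPACE,
        n_iter=n_search,
        cv=cv_folds,
        scoring=make_scorer(mcc),
        random_state=split_seed,
        n_jobs=1,
    )
    search.fit(x_tr, y_tr)
    est = search.best_estimator_
    return TrainedModel(
        estimator=est,
        cv_mcc=float(search.best_score_),
        holdout_mcc=mcc(est.predict(x_te), y_te),
        split_seed=split_seed,
        hyperparameters=dict(search.best_params_),
        feature_ids=list(matrix.columns),
    )


def feature_importance(model: TrainedModel) -> ImportanceRanking:
    """Gain-based importances of the fitted booster, normalized to sum 1,
    ordered descending with ties broken by feature id."""
    imp = np.asarray(model.estimator.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    pairs = sorted(zip(model.feature_ids, imp), key=lambda t: (-t[1], t[0]))
    return ImportanceRanking(tuple((f, float(v)) for f, v in pairs))


def _two_group_cut(x: np.ndarray) -> np.ndarray:
    """Ward/Euclidean hierarchical clustering cut at two groups."""
    z = linkage(x, method="ward", metric="euclidean")
    return fcluster(z, t=2, criterion="maxclust")


def select_cofs(
    ranking: ImportanceRanking,
    matrix: pd.DataFrame,
    clinical: pd.DataFrame,
    min_group_frac: float = 0.30,
    max_prefix: int | None = None,
) -> COFSet:
    """Scan importance prefixes for the best survival stratification.

    For every prefix length m the top-m columns are clustered into two
    groups; prefixes where either group holds fewer than ``min_group_frac``
    of the cohort are inadmissible. Among admissible prefixes the one with
    the smallest log-rank p wins; ties go to the smallest m.
    """
    samples = list(matrix.index)
    clin = clinical.loc[samples]
    times = clin["time_days"].to_numpy(dtype=float)
    events = clin["vital_status"].to_numpy(dtype=int)
    n = len(samples)
    order = ranking.feature_ids
    if set(order) != set(matrix.columns):
        raise ValueError("ranking does not cover the matrix columns")
    m_max = len(order) if max_prefix is None else min(max_prefix, len(order))

    best: tuple[float, int, np.ndarray] | None = None
    x_full = matrix[order].to_numpy(dtype=float)
    for m in range(1, m_max + 1):
        cut = _two_group_cut(x_full[:, :m])
        n1 = int(np.sum(cut == 1))
        if min(n1, n - n1) < min_group_frac * n:
            continue
        res = logrank_test(
            times[cut == 1], times[cut == 2], events[cut == 1], events[cut == 2]
        )
        p = float(res.p_value)
        if best is None or p < best[0]:
            best = (p, m, cut)
    if best is None:
        raise ValueError("no admissible stratification: every prefix violates "
                         f"the {min_group_frac:.0%} minimum group size")
    p, m, cut = best
    grouping = assign_risk_labels(
        pd.Series(cut, index=samples), clin
    )
    selected = order[:m]
    association = classify_cofs(matrix[selected], grouping)
    imp = dict(ranking.entries)
    return COFSet(
        feature_ids=selected,
        best_logrank_p=p,
        grouping=grouping,
        association=association,
        importance={f: imp[f] for f in selected},
    )


def _km_median(times: np.ndarray, events: np.ndarray) -> float:
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    return float(kmf.median_survival_time_)


def _km_final_survival(times: np.ndarray, events: np.ndarray, at: float) -> float:
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    return float(kmf.predict(at))


def assign_risk_labels(grouping: pd.Series, clinical: pd.DataFrame) -> pd.Series:
    """Name the two clusters short-/long-term risk.

    The group with the lower Kaplan-Meier median survival is short-term; if
    both medians are undefined (curves never cross 0.5) the group with lower
    KM survival at the last shared observation time is short-term; an exact
    tie falls back to the smaller group being short.
    """
    ids = sorted(grouping.unique())
    if len(ids) != 2:
        raise ValueError("grouping must have exactly two groups")
    clin = clinical.loc[grouping.index]
    t = clin["time_days"].to_numpy(dtype=float)
    e = clin["vital_status"].to_numpy(dtype=int)
    masks = {g: (grouping == g).to_numpy() for g in ids}
    med = {g: _km_median(t[masks[g]], e[masks[g]]) for g in ids}

    a, b = ids
    if np.isfinite(med[a]) or np.isfinite(med[b]):
        # an undefined (inf) median means better survival than any finite one
        short = a if med[a] < med[b] else b if med[b] < med[a] else None
    else:
        short = None
    if short is None:
        t_shared = min(t[masks[a]].max(), t[masks[b]].max())
        surv = {g: _km_final_survival(t[masks[g]], e[masks[g]], t_shared) for g in ids}
        if surv[a] != surv[b]:
            short = a if surv[a] < surv[b] else b
        else:
            short = a if masks[a].sum() <= masks[b].sum() else b
    return grouping.map(lambda g: SHORT if g == short else LONG)


def classify_cofs(
    matrix: pd.DataFrame,
    grouping: pd.Series,
    alpha: float = 0.05,
) -> dict[str, str]:
    """Associate each feature with the risk group in which it scores higher.

    Welch t-test per column between the short and long groups; p > alpha (or
    an undefined statistic from two degenerate constant groups) leaves the
    feature unassigned.
    """
    short_mask = (grouping.loc[matrix.index] == SHORT).to_numpy()
    out: dict[str, str] = {}
    for feat in matrix.columns:
        x = matrix[feat].to_numpy(dtype=float)
        a, b = x[short_mask], x[~short_mask]
        if np.var(a) == 0 and np.var(b) == 0:
            out[feat] = UNASSIGNED if a.mean() == b.mean() else (
                SHORT if a.mean() > b.mean() else LONG
            )
            continue
        p = stats.ttest_ind(a, b, equal_var=False).pvalue
        if not np.isfinite(p) or p > alpha:
            out[feat] = UNASSIGNED
        else:
            out[feat] = SHORT if a.mean() > b.mean() else LONG
    return out
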