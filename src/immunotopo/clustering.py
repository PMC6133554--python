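"""Optimal cluster number protocol and cross-entity similarity.

The protocol fits three clustering algorithms (Gaussian mixture, k-means,
Ward hierarchical) over k = 1..12 and scores each solution with three
internal criteria (Davies-Bouldin, Calinski-Harabasz, silhouette), with
10 technical replicates per method x criterion.  k = 1 is part of the
scanned range but all three criteria are mathematically undefined there,
so it is recorded as not-evaluable rather than silently skipped — a
"no clustering" solution can therefore never win, which is stated in the
summary metadata.

Entity similarity aggregates percentile-normalized density vectors to
per-entity means and agglomerates them (Euclidean distance, average
linkage by default), exportable as a Newick dendrogram.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import pdist
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.metrics import calinski_harabasz_score, davies_bouldin_score, silhouette_score
from sklearn.mixture import GaussianMixture

log = logging.getLogger(__name__)

METHODS = ("gmm", "kmeans", "hierarchical")
CRITERIA = ("davies_bouldin", "calinski_harabasz", "silhouette")
#: Davies-Bouldin is minimized; the other two are maximized.
_MINIMIZE = {"davies_bouldin"}
DEFAULT_K_RANGE = tuple(range(1, 13))


@dataclass
class ClusterRun:
    """One replicate of one method scored under one criterion."""

    method: str
    criterion: str
    replicate: int
    k_range: tuple[int, ...]
    scores: dict[int, float]
    best_k: int

    def __post_init__(self) -> None:
        if self.best_k not in self.k_range:
            raise ValueError(f"best_k={self.best_k} outside k_range")


def _sub_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([int(seed), *key]).generate_state(1)[0] % (2**31))


def _fit_labels(X: np.ndarray, method: str, k: int, seed: int) -> np.ndarray:
    if method == "kmeans":
        return KMeans(n_clusters=k, n_init=10, init="k-means++", random_state=seed).fit_predict(X)
    if method == "gmm":
        gm = GaussianMixture(
            n_components=k, covariance_type="full", init_params="kmeans", random_state=seed
        )
        return gm.fit_predict(X)
    if method == "hierarchical":
        return AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(X)
    raise ValueError(f"unknown clustering method {method!r}")


def _score(X: np.ndarray, labels: np.ndarray, criterion: str) -> float:
    if len(np.unique(labels)) < 2:
        return float("nan")  # criteria undefined without >= 2 clusters
    try:
        if criterion == "davies_bouldin":
            return float(davies_bouldin_score(X, labels))
        if criterion == "calinski_harabasz":
            return float(calinski_harabasz_score(X, labels))
        if criterion == "silhouette":
            return float(silhouette_score(X, labels))
    except ValueError:
        return float("nan")
    raise ValueError(f"unknown criterion {criterion!r}")


def _impute_means(X: np.ndarray) -> np.ndarray:
    """Mean-impute missing feature values (count logged)."""
    X = np.asarray(X, dtype=float)
    n_missing = int((~np.isfinite(X)).sum())
    if n_missing:
        log.info("mean-imputing %d missing feature values before clustering", n_missing)
        col_means = np.nanmean(np.where(np.isfinite(X), X, np.nan), axis=0)
        idx = np.where(~np.isfinite(X))
        X = X.copy()
        X[idx] = np.take(col_means, idx[1])
    return X


def cluster_scores(
    X: np.ndarray | pd.DataFrame,
    method: str,
    criterion: str,
    k_range: Sequence[int] = DEFAULT_K_RANGE,
    replicates: int = 10,
    seed: int = 0,
) -> list[ClusterRun]:
    """Score k in ``k_range`` for one method x criterion, one run per replicate.

    ``best_k`` maximizes Calinski-Harabasz / silhouette or minimizes
    Davies-Bouldin, ignoring not-evaluable ks (k = 1, degenerate fits).
    Deterministic for a fixed seed.
    """
    X = _impute_means(np.asarray(X, dtype=float))
    k_range = tuple(int(k) for k in k_range)
    if X.shape[0] < max(k_range) + 1:
        raise ValueError(f"need at least {max(k_range) + 1} rows, got {X.shape[0]}")
    method_idx, crit_idx = METHODS.index(method), CRITERIA.index(criterion)
    runs = []
    for rep in range(replicates):
        rep_seed = _sub_seed(seed, method_idx, crit_idx, rep)
        scores: dict[int, float] = {}
        for k in k_range:
            if k < 2:
                scores[k] = float("nan")
                continue
            labels = _fit_labels(X, method, k, rep_seed)
            scores[k] = _score(X, labels, criterion)
        finite = {k: s for k, s in scores.items() if np.isfinite(s)}
        if not finite:
            raise ValueError(f"no evaluable k for method={method}, criterion={criterion}")
        if criterion in _MINIMIZE:
            best_k = min(finite, key=lambda k: (finite[k], k))
        else:
            best_k = min(finite, key=lambda k: (-finite[k], k))
        runs.append(
            ClusterRun(method=method, criterion=criterion, replicate=rep,
                       k_range=k_range, scores=scores, best_k=int(best_k))
        )
    return runs


def run_protocol(
    X: np.ndarray | pd.DataFrame,
    methods: Sequence[str] = METHODS,
    criteria: Sequence[str] = CRITERIA,
    k_range: Sequence[int] = DEFAULT_K_RANGE,
    replicates: int = 10,
    seed: int = 0,
) -> list[ClusterRun]:
    """Full protocol: every method x criterion x replicate."""
    runs: list[ClusterRun] = []
    for method in methods:
        for criterion in criteria:
            runs.extend(cluster_scores(X, method, criterion, k_range, replicates, seed))
    return runs


def _mode_smallest(values: Sequence[int]) -> tuple[int, bool]:
    counts = Counter(values)
    top = max(counts.values())
    winners = sorted(k for k, c in counts.items() if c == top)
    return winners[0], len(winners) > 1


def modal_optimum(runs: Sequence[ClusterRun]) -> tuple[pd.DataFrame, int, bool]:
    """Modal best_k per method x criterion plus the overall mode.

    Ties resolve to the smaller k and are flagged.  Returns
    ``(summary, overall_k, overall_tie)``; the summary carries a note
    that k = 1 is scanned but never evaluable under these criteria.
    """
    if not runs:
        raise ValueError("no cluster runs")
    rows = []
    for (method, criterion), group in pd.DataFrame(
        [(r.method, r.criterion, r.best_k) for r in runs], columns=["method", "criterion", "best_k"]
    ).groupby(["method", "criterion"], sort=True):
        k, tie = _mode_smallest(group["best_k"].tolist())
        rows.append((method, criterion, k, tie, len(group)))
    summary = pd.DataFrame(rows, columns=["method", "criterion", "modal_k", "tie", "n_runs"])
    summary.attrs["note"] = (
        "k=1 is scanned but not evaluable under Davies-Bouldin, Calinski-Harabasz "
        "or silhouette; the modal optimum is over k >= 2."
    )
    overall_k, overall_tie = _mode_smallest([r.best_k for r in runs])
    return summary, overall_k, overall_tie


def runs_to_frame(runs: Sequence[ClusterRun]) -> pd.DataFrame:
    """Long export: method, criterion, replicate, k, score, best_k."""
    rows = []
    for r in runs:
        for k, s in r.scores.items():
            rows.append((r.method, r.criterion, r.replicate, k, s, r.best_k))
    return pd.DataFrame(rows, columns=["method", "criterion", "replicate", "k", "score", "best_k"])


# ---------------------------------------------------------------------------
# Cross-entity similarity


@dataclass
class EntityLinkage:
    """Agglomeration of tumor entities on mean feature vectors."""

    leaves: tuple[str, ...]
    merge_tree: np.ndarray  # scipy linkage matrix, heights non-decreasing
    linkage_method: str
    distance_metric: str
    entity_means: pd.DataFrame = field(repr=False, default=None)

    def to_newick(self, precision: int = 6) -> str:
        return linkage_to_newick(self.merge_tree, list(self.leaves), precision=precision)


def entity_similarity(
    X: pd.DataFrame,
    entities: Mapping[str, str] | pd.Series,
    linkage_method: str = "average",
    distance_metric: str = "euclidean",
) -> EntityLinkage:
    """Hierarchically cluster tumor entities by mean immune-topography vectors.

    ``X`` holds one percentile-normalized feature vector per patient
    (markers x compartments); patients with any missing feature are
    dropped (the similarity analysis requires the full panel), and
    entities left with no complete patient are excluded with a warning.
    """
    ent = pd.Series(entities).reindex(X.index)
    complete = X.notna().all(axis=1)
    if not complete.any():
        raise ValueError("no patients with a complete feature vector")
    dropped_entities = set(ent.unique()) - set(ent[complete].unique())
    if dropped_entities:
        log.warning("entities with no complete patients excluded: %s", sorted(dropped_entities))
    means = X[complete].groupby(ent[complete]).mean().sort_index()
    if len(means) < 2:
        raise ValueError("need at least two entities to agglomerate")
    dist = pdist(means.to_numpy(float), metric=distance_metric)
    Z = scipy_linkage(dist, method=linkage_method)
    return EntityLinkage(
        leaves=tuple(means.index), merge_tree=Z,
        linkage_method=linkage_method, distance_metric=distance_metric,
        entity_means=means,
    )


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str], precision: int = 6) -> str:
    """Newick string for a scipy linkage matrix.

    Node depths equal merge heights (branch length = parent height minus
    child height), so the tree is ultrametric with leaves at depth 0.
    """
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    for j, (a, b, h, _) in enumerate(Z):
        heights[n + j] = float(h)

    def emit(node: int, parent_h: float) -> str:
        blen = parent_h - heights[node]
        if node < n:
            return f"{labels[node]}:{blen:.{precision}g}"
        a, b = int(Z[node - n, 0]), int(Z[node - n, 1])
        h = heights[node]
        return f"({emit(a, h)},{emit(b, h)}):{blen:.{precision}g}"

    root = n + len(Z) - 1
    return emit(root, heights[root]) + ";"
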