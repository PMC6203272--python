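"""Evaluation mathematics for clustering results.

Implements the dispersion metric (MSE), the trimmed boundary boxes and the
modified Jaccard index (JI) built on them, the adjusted Rand index, seven
whole-partition cluster validation indices, and the tie-averaged rank
score that compares methods across those indices.

Conventions
-----------
* MSE of a cluster of N genes in a D-dimensional dataset is the summed
  squared Euclidean distance of member profiles to the cluster mean
  profile, normalized by both D and N:  MSE = (1/(D*N)) * sum_g ||x_g - z||^2.
* The MSE of a whole result is the size-weighted average of cluster MSEs.
* A cluster's boundary box is, per condition, the [1st, 99th] percentile
  interval of member values ("trimming the most extreme 1% of values at
  each point"); a gene is an overlap gene when it belongs to one cluster
  but lies inside the box of at least one *other* cluster at every
  condition.  JI = overlap genes / all genes in clusters.
* Index directions: larger is better for BIC, silhouette and CH; smaller
  is better for DB, BH, Xu and WB.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import (
    adjusted_rand_score,
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .io_model import ClusterResult, ExpressionMatrix, Partition, ValidationError

INDEX_NAMES = ("DB", "BIC", "silhouette", "CH", "BH", "Xu", "WB")
LARGER_BETTER = frozenset({"BIC", "silhouette", "CH"})
SMALLER_BETTER = frozenset({"DB", "BH", "Xu", "WB"})


def _gene_sets(obj: ClusterResult | Partition | Sequence[Iterable[str]]) -> list[set[str]]:
    if isinstance(obj, ClusterResult):
        return obj.gene_sets()
    if isinstance(obj, Partition):
        return [c for c in obj.clusters() if c]
    return [set(c) for c in obj]


# ---------------------------------------------------------------------------
# Dispersion (MSE)
# ---------------------------------------------------------------------------


def cluster_mse(cluster: Iterable[str], m: ExpressionMatrix) -> float:
    """Within-cluster dispersion, normalized by dimensions and cluster size."""
    genes = sorted(cluster)
    if not genes:
        raise ValidationError("MSE of an empty cluster is undefined")
    X = m.profiles(genes)
    z = X.mean(axis=0)
    return float(((X - z) ** 2).sum() / (m.n_conditions * len(genes)))


def result_mse(result: ClusterResult | Sequence[Iterable[str]], m: ExpressionMatrix) -> float:
    """Size-weighted average of per-cluster MSE over a whole result."""
    sets = _gene_sets(result)
    if not sets:
        raise ValidationError("MSE of a result with no clusters is undefined")
    sizes = np.array([len(c) for c in sets], dtype=float)
    mses = np.array([cluster_mse(c, m) for c in sets])
    return float((sizes * mses).sum() / sizes.sum())


# ---------------------------------------------------------------------------
# Boundary boxes and JI
# ---------------------------------------------------------------------------


@dataclass
class BoundaryBox:
    """Per-condition [lower, upper] value intervals for one cluster."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if (self.lower > self.upper).any():
            raise ValidationError("boundary box has lower > upper")

    def contains(self, profile: np.ndarray) -> bool:
        """True iff the profile lies inside the box at every condition."""
        return bool((profile >= self.lower).all() and (profile <= self.upper).all())


def boundary_box(cluster: Iterable[str], m: ExpressionMatrix) -> BoundaryBox:
    """Trimmed extent of a cluster: per-condition 1st..99th percentile."""
    genes = sorted(cluster)
    if not genes:
        raise ValidationError("boundary box of an empty cluster is undefined")
    X = m.profiles(genes)
    return BoundaryBox(np.percentile(X, 1, axis=0), np.percentile(X, 99, axis=0))


def overlap_genes(
    clusters: Sequence[Iterable[str]], matrices: Sequence[ExpressionMatrix]
) -> set[str]:
    """Genes inside another cluster's box at every condition of every dataset."""
    sets = [set(c) for c in clusters]
    boxes = [[boundary_box(c, m) for c in sets] for m in matrices]
    out: set[str] = set()
    for a, members in enumerate(sets):
        for g in members:
            profs = [m.profiles([g])[0] for m in matrices]
            for b in range(len(sets)):
                if b == a:
                    continue
                if all(boxes[i][b].contains(p) for i, p in enumerate(profs)):
                    out.add(g)
                    break
    return out


def ji(result: ClusterResult | Sequence[Iterable[str]], m: ExpressionMatrix) -> float:
    """Fraction of clustered genes that also fit inside another cluster's box.

    0 means perfectly distinct clusters; a single-cluster (or empty) result
    has JI 0 by convention since no "other cluster" exists.
    """
    sets = _gene_sets(result)
    total = sum(len(c) for c in sets)
    if total == 0 or len(sets) < 2:
        return 0.0
    return len(overlap_genes(sets, [m])) / total


# ---------------------------------------------------------------------------
# Adjusted Rand index
# ---------------------------------------------------------------------------


def adjusted_rand_index(p: Partition, q: Partition) -> float:
    """Standard pair-counting ARI between two assignments of one gene set.

    Both partitions must cover the same gene universe.  Unassigned genes
    (cluster-extraction results need not cover every gene) are treated as
    one extra group so that extraction results remain comparable.
    """
    if p.genes != q.genes:
        raise ValidationError("partitions cover different gene universes")
    genes = sorted(p.genes)
    a = [p.labels[g] for g in genes]
    b = [q.labels[g] for g in genes]
    return float(adjusted_rand_score(a, b))


# ---------------------------------------------------------------------------
# Validation indices
# ---------------------------------------------------------------------------


@dataclass
class IndexScores:
    """The seven validation-index values for one method's result.

    Indices that are undefined for the result (e.g. separation-based
    indices of a single-cluster result) hold ``nan`` and rank worst.
    """

    method: str
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(INDEX_NAMES)
        if unknown:
            raise ValidationError(f"unknown index names: {sorted(unknown)}")
        for name in INDEX_NAMES:
            self.values.setdefault(name, math.nan)


def _spherical_bic(X: np.ndarray, labels: np.ndarray, K: int) -> float:
    """BIC under a spherical-Gaussian mixture of the K clusters (larger better)."""
    n, D = X.shape
    if n <= K:
        return math.nan
    W = 0.0
    counts = np.zeros(K)
    for k in range(K):
        mem = X[labels == k]
        counts[k] = len(mem)
        W += ((mem - mem.mean(axis=0)) ** 2).sum()
    var = W / (D * (n - K))
    if var <= 0:  # degenerate: all members identical -> likelihood unbounded
        var = np.finfo(float).tiny
    log_l = (
        float((counts * np.log(counts / n)).sum())
        - 0.5 * n * D * math.log(2 * math.pi * var)
        - 0.5 * D * (n - K)
    )
    n_params = K * (D + 1)
    return log_l - 0.5 * n_params * math.log(n)


def validation_indices(
    obj: ClusterResult | Partition | Sequence[Iterable[str]],
    m: ExpressionMatrix,
    method: str = "",
) -> IndexScores:
    """Compute DB, BIC, silhouette, CH, BH, Xu and WB for one result.

    Only assigned genes enter the computation; Euclidean distance is used
    throughout.  Indices requiring between-cluster separation (DB,
    silhouette, CH, WB) are ``nan`` for results with fewer than two
    clusters.
    """
    sets = [c for c in _gene_sets(obj) if c]
    K = len(sets)
    vals: dict[str, float] = {}
    if K == 0:
        return IndexScores(method, vals)
    genes = [g for c in sets for g in sorted(c)]
    labels = np.concatenate([np.full(len(c), k) for k, c in enumerate(sets)])
    X = m.profiles(genes)
    n, D = X.shape

    centroids = np.stack([X[labels == k].mean(axis=0) for k in range(K)])
    W = sum(float(((X[labels == k] - centroids[k]) ** 2).sum()) for k in range(K))
    grand = X.mean(axis=0)
    B = float(
        sum((labels == k).sum() * ((centroids[k] - grand) ** 2).sum() for k in range(K))
    )

    vals["BIC"] = _spherical_bic(X, labels, K)
    vals["BH"] = float(
        np.mean([((X[labels == k] - centroids[k]) ** 2).sum() / (labels == k).sum() for k in range(K)])
    )
    # Xu index: dimensionality-weighted log of the within-cluster scatter density.
    vals["Xu"] = (
        D * math.log2(math.sqrt(W / (D * n * n))) + math.log2(K) if W > 0 else -math.inf
    )
    if K >= 2 and n > K:
        vals["DB"] = float(davies_bouldin_score(X, labels))
        vals["CH"] = float(calinski_harabasz_score(X, labels))
        vals["WB"] = K * W / B if B > 0 else math.nan
        try:
            vals["silhouette"] = float(silhouette_score(X, labels))
        except ValueError:
            vals["silhouette"] = math.nan
    return IndexScores(method, vals)


# ---------------------------------------------------------------------------
# Rank scores
# ---------------------------------------------------------------------------


@dataclass
class RankReport:
    """Tie-averaged ranks of competing methods on one dataset.

    ``ranks[index][method]`` is the method's rank for that index (1 = best,
    n_methods = worst, ties averaged); ``final[method]`` is the mean of the
    method's seven per-index ranks.
    """

    methods: list[str]
    ranks: dict[str, dict[str, float]]
    final: dict[str, float]


def rank_scores(scores: Sequence[IndexScores]) -> RankReport:
    """Convert raw index values into direction-aware, tie-averaged ranks.

    Undefined (``nan``) index values rank worst; ties — including ties
    among several undefined values — receive averaged ranks, so each
    index's ranks are a tie-averaged permutation of ``1..n_methods``.
    """
    if len(scores) < 2:
        raise ValidationError("rank scores need at least two methods")
    methods = [s.method for s in scores]
    if len(set(methods)) != len(methods):
        raise ValidationError("method labels must be unique")
    ranks: dict[str, dict[str, float]] = {}
    for index in INDEX_NAMES:
        keys = np.array(
            [
                s.values[index] if index in SMALLER_BETTER else -s.values[index]
                for s in scores
            ]
        )
        keys = np.where(np.isnan(keys), np.inf, keys)  # undefined ranks worst
        r = rankdata(keys, method="average")
        ranks[index] = {meth: float(rv) for meth, rv in zip(methods, r)}
    final = {
        meth: float(np.mean([ranks[index][meth] for index in INDEX_NAMES]))
        for meth in methods
    }
    return RankReport(methods, ranks, final)


# ---------------------------------------------------------------------------
# Result summarization
# ---------------------------------------------------------------------------


def summarize_result(
    clusters: Sequence[Iterable[str]],
    matrices: Sequence[ExpressionMatrix],
    n_retained: int,
) -> ClusterResult:
    """Build a :class:`ClusterResult` with its metric fields populated.

    Per-cluster MSE (and the weighted overall MSE) are averaged across the
    input datasets; JI counts genes lying inside another cluster's box in
    every dataset, which for a single dataset is exactly the JI metric.
    """
    sets = [set(c) for c in clusters if c]
    if not sets:
        return ClusterResult([], n_retained=n_retained, per_cluster_mse=[], overall_mse=0.0, ji=0.0, pag=0.0)
    per_cluster = [
        float(np.mean([cluster_mse(c, m) for m in matrices])) for c in sets
    ]
    sizes = np.array([len(c) for c in sets], dtype=float)
    overall = float((sizes * np.array(per_cluster)).sum() / sizes.sum())
    n_assigned = int(sizes.sum())
    ji_val = (
        len(overlap_genes(sets, matrices)) / n_assigned if len(sets) >= 2 else 0.0
    )
    pag = 100.0 * n_assigned / n_retained if n_retained else 0.0
    return ClusterResult(
        [tuple(sorted(c)) for c in sets],
        n_retained=n_retained,
        per_cluster_mse=per_cluster,
        overall_mse=overall,
        ji=ji_val,
        pag=pag,
    )
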