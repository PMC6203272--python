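"""Seed-cluster pool generation.

A "seed cluster" is a candidate gene set produced before selection and
refinement.  For a single dataset the pool is simply every cluster of the
best-of-restarts k-means partition at each K on a grid of K values.  For
multiple datasets the per-dataset partitions at each K are combined by the
Bi-CoPaM consensus scheme: partitions are aligned by optimal label
matching, averaged into a fuzzy consensus partition matrix (CPM), and
binarized with the difference-threshold operator (DTB) at each δ of a grid
— a gene joins a consensus cluster only when its membership exceeds the
runner-up's by more than δ, so larger δ keeps only the genes consistently
co-clustered across datasets.

Everything here is deterministic given ``SeedConfig.seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .io_model import ExpressionMatrix, Partition, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_K_GRID = tuple(range(2, 21, 2))
DEFAULT_DELTA_GRID = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)


def _sub_seed(seed: int, *parts: int) -> int:
    """Derive a stable 31-bit child seed from a base seed and integer tags."""
    out = seed & 0x7FFFFFFF
    for p in parts:
        out = (out * 1_000_003 + p * 7_919 + 12_345) % (2**31)
    return out


@dataclass
class SeedConfig:
    """Parameters of seed-pool generation.

    k_grid:
        Cluster counts to try; values at or above the retained gene count
        are skipped with a warning.  The default 2..20 (step 2) spans the
        cluster counts typical of bulk expression datasets.
    restarts:
        k-means restarts per K; the restart with the lowest within-cluster
        sum of squares wins.
    delta_grid:
        DTB thresholds used in the multi-dataset consensus path, ascending
        in [0, 1].  High δ values yield empty seeds, so the default stops
        at 0.5.
    """

    k_grid: tuple[int, ...] = DEFAULT_K_GRID
    restarts: int = 10
    seed: int = 0
    delta_grid: tuple[float, ...] = DEFAULT_DELTA_GRID

    def __post_init__(self) -> None:
        self.k_grid = tuple(int(k) for k in self.k_grid)
        self.delta_grid = tuple(float(d) for d in self.delta_grid)
        if any(k < 1 for k in self.k_grid):
            raise ValidationError("k_grid values must be >= 1")
        if any(not 0.0 <= d <= 1.0 for d in self.delta_grid):
            raise ValidationError("delta_grid values must lie in [0, 1]")
        if list(self.delta_grid) != sorted(self.delta_grid):
            raise ValidationError("delta_grid must be sorted ascending")
        if self.restarts < 1:
            raise ValidationError("restarts must be >= 1")


@dataclass(frozen=True)
class SeedCluster:
    """A candidate gene set with a record of how it was produced."""

    genes: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError("seed cluster has no genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class FuzzyCPM:
    """Fuzzy consensus partition matrix: genes x K memberships in [0, 1].

    Each row is the average of the aligned one-hot membership rows of the
    contributing partitions, so rows sum to 1.
    """

    gene_ids: list[str]
    memberships: np.ndarray

    def __post_init__(self) -> None:
        self.memberships = np.asarray(self.memberships, dtype=float)
        if self.memberships.ndim != 2 or self.memberships.shape[0] != len(self.gene_ids):
            raise ValidationError("membership matrix shape does not match gene ids")
        if (self.memberships < -1e-12).any() or (self.memberships > 1 + 1e-12).any():
            raise ValidationError("memberships must lie in [0, 1]")
        if not np.allclose(self.memberships.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("membership rows must sum to 1")

    @property
    def K(self) -> int:
        return self.memberships.shape[1]


# ---------------------------------------------------------------------------
# k-means
# ---------------------------------------------------------------------------


def kmeans_partition(m: ExpressionMatrix, K: int, restarts: int, seed: int) -> Partition:
    """Best-of-restarts Euclidean k-means partition of the matrix rows."""
    if K >= m.n_genes and K != 1:
        raise ValidationError(f"K={K} not below gene count {m.n_genes}")
    km = KMeans(
        n_clusters=K,
        n_init=restarts,
        init="k-means++",
        algorithm="lloyd",
        random_state=seed,
    ).fit(m.values)
    labels = {g: int(lab) for g, lab in zip(m.gene_ids, km.labels_)}
    return Partition(labels, K=K)


def kmeans_pool(m: ExpressionMatrix, cfg: SeedConfig) -> list[SeedCluster]:
    """Single-dataset seed pool: every cluster of every K on the grid."""
    pool: list[SeedCluster] = []
    for K in cfg.k_grid:
        if K >= m.n_genes and K != 1:
            logger.warning("skipping K=%d: not below gene count %d", K, m.n_genes)
            continue
        part = kmeans_partition(m, K, cfg.restarts, _sub_seed(cfg.seed, K))
        for k, genes in enumerate(part.clusters()):
            if genes:
                pool.append(SeedCluster(frozenset(genes), source=f"K={K},c{k}"))
    return pool


# ---------------------------------------------------------------------------
# Bi-CoPaM consensus
# ---------------------------------------------------------------------------


def align_partitions(reference: Partition, other: Partition) -> Partition:
    """Relabel ``other`` to best match ``reference``.

    Solves the optimal one-to-one assignment on the K x K gene-overlap
    matrix (maximizing total overlap), so the returned partition has the
    same clusters as ``other`` under reference-compatible labels.
    """
    if reference.K != other.K:
        raise ValidationError(f"cannot align partitions with K={reference.K} and K={other.K}")
    if reference.genes != other.genes:
        raise ValidationError("partitions cover different gene universes")
    K = reference.K
    overlap = np.zeros((K, K))
    for g, lab in other.labels.items():
        ref_lab = reference.labels[g]
        if lab >= 0 and ref_lab >= 0:
            overlap[ref_lab, lab] += 1
    ref_idx, other_idx = linear_sum_assignment(-overlap)
    relabel = {int(j): int(i) for i, j in zip(ref_idx, other_idx)}
    labels = {g: relabel[lab] if lab >= 0 else lab for g, lab in other.labels.items()}
    return Partition(labels, K=K)


def build_cpm(aligned: Sequence[Partition]) -> FuzzyCPM:
    """Average aligned one-hot memberships into a fuzzy consensus matrix."""
    if not aligned:
        raise ValidationError("need at least one partition")
    K = aligned[0].K
    universe = aligned[0].genes
    for p in aligned[1:]:
        if p.K != K or p.genes != universe:
            raise ValidationError("partitions must share K and gene universe")
    gene_ids = sorted(universe)
    mem = np.zeros((len(gene_ids), K))
    for p in aligned:
        for i, g in enumerate(gene_ids):
            lab = p.labels[g]
            if lab < 0:
                raise ValidationError("consensus requires fully assigned partitions")
            mem[i, lab] += 1.0
    mem /= len(aligned)
    return FuzzyCPM(gene_ids, mem)


def dtb_binarize(cpm: FuzzyCPM, delta: float, source: str = "") -> list[SeedCluster]:
    """Difference-threshold binarization of a consensus matrix.

    A gene is assigned to its top-membership cluster only when that
    membership exceeds the runner-up's by strictly more than δ; exact ties
    stay unassigned for every δ ≥ 0.  Empty clusters are dropped.
    """
    if not 0.0 <= delta <= 1.0:
        raise ValidationError(f"delta {delta} outside [0, 1]")
    clusters: list[set[str]] = [set() for _ in range(cpm.K)]
    for g, row in zip(cpm.gene_ids, cpm.memberships):
        top = int(np.argmax(row))
        others = np.delete(row, top)
        margin = row[top] - (others.max() if others.size else 0.0)
        if margin > delta:
            clusters[top].add(g)
    return [
        SeedCluster(frozenset(c), source=f"{source}δ={delta:g},c{k}")
        for k, c in enumerate(clusters)
        if c
    ]


def shared_universe(matrices: Sequence[ExpressionMatrix]) -> list[str]:
    """Genes retained in every dataset, ordered as in the first dataset."""
    common = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        common &= set(m.gene_ids)
    if not common:
        raise ValidationError(
            "datasets share no genes after pre-processing: "
            + ", ".join(m.dataset_id for m in matrices)
        )
    return [g for g in matrices[0].gene_ids if g in common]


def multi_dataset_seed_pool(
    matrices: Sequence[ExpressionMatrix], cfg: SeedConfig
) -> list[SeedCluster]:
    """Consensus seed pool over two or more datasets.

    For each K: k-means per dataset on the shared gene universe, alignment
    of all partitions to the first dataset's, CPM construction, and DTB
    binarization at every δ of the grid.  The pool is the union of the
    resulting seeds over K and δ.
    """
    if len(matrices) < 2:
        raise ValidationError("multi-dataset consensus needs at least two datasets")
    universe = shared_universe(matrices)
    subs = [m.subset(universe) for m in matrices]
    pool: list[SeedCluster] = []
    for K in cfg.k_grid:
        if K >= len(universe) and K != 1:
            logger.warning("skipping K=%d: not below shared gene count %d", K, len(universe))
            continue
        parts = [
            kmeans_partition(sub, K, cfg.restarts, _sub_seed(cfg.seed, K, i))
            for i, sub in enumerate(subs)
        ]
        aligned = [parts[0]] + [align_partitions(parts[0], p) for p in parts[1:]]
        cpm = build_cpm(aligned)
        for delta in cfg.delta_grid:
            pool.extend(dtb_binarize(cpm, delta, source=f"K={K},"))
    return pool
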