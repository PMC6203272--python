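"""Cluster optimization: outlier removal, completion, and distinctness.

The elite seeds coming out of M-N selection are treated as first drafts.
This module learns the distribution of within-cluster dispersion from the
elites themselves and uses it to (a) strip genes that do not belong,
(b) pull in retained genes the earlier steps missed, and (c) guarantee
that the final clusters are mutually exclusive in profile space (JI = 0).

Two complementary outlier rules are applied, both controlled by the
tightness multiplier ``q`` (default 3.0; smaller means tighter clusters):

* **Per-cluster envelope** — a gene fits a cluster when its value lies
  within mean ± q·std of the members at every condition of every dataset
  (exact equality required where the member std is zero).
* **Pooled dispersion gate** — the per-gene deviations from their cluster
  mean profiles, pooled over *all* clusters, form the learned dispersion
  distribution; genes whose deviation exceeds a robust upper bound
  (median + q · 1.4826 · MAD) of that distribution are outliers even if
  their own cluster is loose.  This is what dissolves pseudo-clusters
  assembled from genes that merely happened to land in the same k-means
  cell: their members are collectively far more dispersed than members of
  genuine co-expression clusters, so the pooled gate removes them and the
  cluster collapses below the minimum size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_model import ClusterResult, ExpressionMatrix, ValidationError
from .metrics import boundary_box, summarize_result
from .seeds import SeedCluster, shared_universe
from .selection import DEFAULT_MIN_SIZE

DEFAULT_TIGHTNESS = 3.0
DEFAULT_MAX_ITER = 20

#: Absolute slack used where a zero member std demands exact equality.
_EXACT_TOL = 1e-9


@dataclass
class ClusterEnvelope:
    """Per-dataset, per-condition Gaussian envelope of one cluster.

    ``means[dataset_id]`` and ``stds[dataset_id]`` are length-D arrays of
    the member mean and population std at each condition; a gene fits when
    it deviates from the mean by at most ``q`` member-stds everywhere.
    """

    means: dict[str, np.ndarray]
    stds: dict[str, np.ndarray]
    q: float

    def __post_init__(self) -> None:
        if self.q <= 0:
            raise ValidationError("envelope multiplier q must be > 0")
        for ds, s in self.stds.items():
            if (np.asarray(s) < 0).any():
                raise ValidationError(f"negative std in envelope for dataset {ds!r}")


def cluster_envelope(
    genes: Iterable[str], matrices: Sequence[ExpressionMatrix], q: float
) -> ClusterEnvelope:
    """Learn a cluster's envelope from its current members."""
    ids = sorted(genes)
    if not ids:
        raise ValidationError("cannot build an envelope from an empty cluster")
    means, stds = {}, {}
    for m in matrices:
        X = m.profiles(ids)
        means[m.dataset_id] = X.mean(axis=0)
        stds[m.dataset_id] = X.std(axis=0)
    return ClusterEnvelope(means, stds, q)


def fits(gene: str, env: ClusterEnvelope, matrices: Sequence[ExpressionMatrix]) -> bool:
    """True iff the gene lies inside the envelope in every dataset.

    Conditions with zero member std admit only (numerically) exact
    equality, so a σ=0 cluster accepts precisely its own profile.
    """
    for m in matrices:
        x = m.profiles([gene])[0]
        mu, s = env.means[m.dataset_id], env.stds[m.dataset_id]
        tol = np.where(s == 0.0, _EXACT_TOL, env.q * s)
        if (np.abs(x - mu) > tol).any():
            return False
    return True


# ---------------------------------------------------------------------------
# Pooled dispersion gate
# ---------------------------------------------------------------------------


def _deviations(
    clusters: Sequence[set[str]], matrices: Sequence[ExpressionMatrix]
) -> dict[str, float]:
    """Per-gene deviation from its cluster mean profile.

    The deviation is the Euclidean distance to the member mean, normalized
    by sqrt(D) (so it is a per-condition RMS deviation) and averaged over
    datasets.
    """
    out: dict[str, float] = {}
    for members in clusters:
        ids = sorted(members)
        per_ds = []
        for m in matrices:
            X = m.profiles(ids)
            z = X.mean(axis=0)
            per_ds.append(np.sqrt(((X - z) ** 2).sum(axis=1) / m.n_conditions))
        dev = np.mean(per_ds, axis=0)
        out.update(zip(ids, dev))
    return out


def dispersion_threshold(deviations: Iterable[float], q: float) -> float:
    """Robust upper bound of the pooled dispersion distribution.

    median + q * 1.4826 * MAD — the MAD-based analogue of a mean + q·std
    bound under normality, insensitive to the heavy tail contributed by
    spurious clusters.
    """
    r = np.asarray(list(deviations), dtype=float)
    med = float(np.median(r))
    mad = float(np.median(np.abs(r - med)))
    return med + q * 1.4826 * mad


# ---------------------------------------------------------------------------
# Refinement passes
# ---------------------------------------------------------------------------


def remove_outliers(
    clusters: Sequence[Iterable[str]],
    matrices: Sequence[ExpressionMatrix],
    q: float = DEFAULT_TIGHTNESS,
    min_size: int = DEFAULT_MIN_SIZE,
    max_passes: int = 100,
) -> list[set[str]]:
    """Iteratively strip genes failing either outlier rule until stable.

    Envelopes and the pooled dispersion distribution are recomputed from
    the surviving members at every pass; clusters shrinking below
    ``min_size`` are deleted.
    """
    current = [set(c) for c in clusters if c]
    for _ in range(max_passes):
        current = [c for c in current if len(c) >= min_size]
        if not current:
            return []
        devs = _deviations(current, matrices)
        thresh = dispersion_threshold(devs.values(), q)
        envs = [cluster_envelope(c, matrices, q) for c in current]
        nxt = [
            {
                g
                for g in c
                if devs[g] <= thresh + _EXACT_TOL and fits(g, env, matrices)
            }
            for c, env in zip(current, envs)
        ]
        if nxt == current:
            break
        current = nxt
    return [c for c in current if len(c) >= min_size]


def complete_clusters(
    clusters: Sequence[Iterable[str]],
    matrices: Sequence[ExpressionMatrix],
    q: float = DEFAULT_TIGHTNESS,
    universe: Sequence[str] | None = None,
) -> list[set[str]]:
    """Add unassigned genes that unambiguously fit one cluster.

    Every retained-but-unassigned gene is tested against each cluster's
    envelope (as learned *before* any additions); it joins a cluster only
    when it fits exactly one — a gene fitting two or more stays unassigned
    so that distinctness is never eroded.
    """
    current = [set(c) for c in clusters if c]
    if not current:
        return []
    universe = universe if universe is not None else shared_universe(matrices)
    assigned = set().union(*current)
    envs = [cluster_envelope(c, matrices, q) for c in current]
    for g in universe:
        if g in assigned:
            continue
        hits = [k for k, env in enumerate(envs) if fits(g, env, matrices)]
        if len(hits) == 1:
            current[hits[0]].add(g)
    return current


def enforce_distinctness(
    clusters: Sequence[Iterable[str]],
    matrices: Sequence[ExpressionMatrix],
    min_size: int = DEFAULT_MIN_SIZE,
) -> list[set[str]]:
    """Remove overlap genes until the boundary boxes are mutually exclusive.

    A gene sitting in one cluster while lying inside another cluster's
    trimmed boundary box (at every condition of every dataset) is
    ambiguous by construction and is discarded, not reassigned.  Boxes are
    recomputed after each pass; since every pass removes at least one
    assigned gene, the loop terminates in at most (total assigned genes)
    passes and the returned clusters have JI = 0.
    """
    current = [set(c) for c in clusters if len(set(c)) >= min_size]
    while len(current) >= 2:
        boxes = [
            [boundary_box(c, m) for c in current] for m in matrices
        ]
        overlap: set[str] = set()
        for a, members in enumerate(current):
            for g in members:
                profs = [m.profiles([g])[0] for m in matrices]
                if any(
                    b != a and all(boxes[i][b].contains(p) for i, p in enumerate(profs))
                    for b in range(len(current))
                ):
                    overlap.add(g)
        if not overlap:
            break
        current = [c - overlap for c in current]
        current = [c for c in current if len(c) >= min_size]
    return current


def refine(
    clusters: Sequence[SeedCluster] | Sequence[Iterable[str]],
    matrices: Sequence[ExpressionMatrix],
    q: float = DEFAULT_TIGHTNESS,
    max_iter: int = DEFAULT_MAX_ITER,
    min_size: int = DEFAULT_MIN_SIZE,
    universe: Sequence[str] | None = None,
) -> ClusterResult:
    """Optimize and complete elite clusters into the final result.

    Alternates outlier removal and completion until the membership reaches
    a fixed point (or ``max_iter`` rounds), then enforces boundary-box
    distinctness.  The returned :class:`ClusterResult` carries MSE, JI
    (always 0), PAG and K; an empty elite list yields an empty result with
    PAG = 0.
    """
    if max_iter < 1:
        raise ValidationError("max_iter must be >= 1")
    sets = [
        set(c.genes) if isinstance(c, SeedCluster) else set(c) for c in clusters
    ]
    universe = list(universe) if universe is not None else shared_universe(matrices)
    current = [c for c in sets if c]
    for _ in range(max_iter):
        previous = [set(c) for c in current]
        current = remove_outliers(current, matrices, q, min_size)
        current = complete_clusters(current, matrices, q, universe)
        if current == previous:
            break
    current = enforce_distinctness(current, matrices, min_size)
    return summarize_result(current, matrices, n_retained=len(universe))
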