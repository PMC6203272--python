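"""Elite-cluster selection by the M-N scatter technique.

Every seed cluster is placed on a plane spanned by its dispersion M (mean
per-dataset cluster MSE) and its size N (gene count).  After min-max
scaling M and log2(N) over the current pool, the seed nearest the ideal
corner (M_scaled = 0, N_scaled = 1) is selected as an elite; its genes are
deleted from every remaining seed, scalings are recomputed, and the
process repeats until no eligible seed survives.  Gene deletion guarantees
the selected elites are pairwise disjoint, and the ideal-corner distance
favours large clusters with low dispersion.

Eligibility demands more than a minimum size: a seed also has to be
substantially tighter than the dataset as a whole.  Because the M axis is
min-max rescaled over the *surviving* pool, the iteration would otherwise
eventually elect every leftover seed — including groups of genes that
merely shared a k-means cell without co-varying.  The dispersion cap
(default: cluster MSE at most half the MSE of the whole retained gene set)
expresses the minimal requirement that a reported cluster explain at
least half of its members' variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_model import ExpressionMatrix, ValidationError
from .metrics import cluster_mse
from .seeds import SeedCluster, shared_universe

DEFAULT_MIN_SIZE = 10

#: Default dispersion cap, as a fraction of the data-wide dispersion.
DEFAULT_DISPERSION_CAP = 0.5


@dataclass
class MNPoint:
    """One seed's position on the dispersion-size plane."""

    seed: SeedCluster
    M: float
    N: int
    M_scaled: float
    N_scaled: float
    distance: float


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:  # degenerate pool: everything scales to 0
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def mn_points(
    pool: Sequence[SeedCluster],
    matrices: Sequence[ExpressionMatrix],
    weight: float = 1.0,
) -> list[MNPoint]:
    """Score every seed in the pool against the current pool's spread.

    ``weight`` (w in (0, 2)) tilts the ideal-corner distance
    ``sqrt(w * M_scaled^2 + (2 - w) * (1 - N_scaled)^2)`` between
    tightness (w > 1) and size (w < 1); the default weighs them equally.
    """
    if not pool:
        return []
    if not 0.0 < weight < 2.0:
        raise ValidationError(f"mn weight {weight} outside (0, 2)")
    M = np.array(
        [
            float(np.mean([cluster_mse(s.genes, m) for m in matrices]))
            for s in pool
        ]
    )
    N = np.array([len(s) for s in pool], dtype=float)
    M_scaled = _minmax(M)
    N_scaled = _minmax(np.log2(N))
    dist = np.sqrt(weight * M_scaled**2 + (2.0 - weight) * (1.0 - N_scaled) ** 2)
    return [
        MNPoint(s, float(m_), int(n_), float(ms), float(ns), float(d))
        for s, m_, n_, ms, ns, d in zip(pool, M, N, M_scaled, N_scaled, dist)
    ]


def _tie_key(p: MNPoint) -> tuple[float, int, tuple[str, ...]]:
    # smallest distance wins; ties -> larger N, then smallest sorted gene tuple
    return (p.distance, -p.N, tuple(sorted(p.seed.genes)))


def select_elites(
    pool: Sequence[SeedCluster],
    matrices: Sequence[ExpressionMatrix],
    min_size: int = DEFAULT_MIN_SIZE,
    weight: float = 1.0,
    dispersion_cap: float | None = DEFAULT_DISPERSION_CAP,
) -> list[SeedCluster]:
    """Iteratively pick disjoint elite seeds from the pool.

    Each round rescores the surviving seeds (so earlier deletions
    propagate into both M and N), takes the minimum-distance seed, and
    deletes its genes from every survivor; seeds falling below
    ``min_size`` — or, when ``dispersion_cap`` is set, whose dispersion M
    exceeds ``dispersion_cap`` times the whole retained gene set's MSE —
    drop out.  Deterministic: ties on distance break by larger size, then
    by lexicographically smallest gene tuple.  ``dispersion_cap=None``
    disables the quality floor and reproduces the plain M-N iteration.
    """
    if min_size < 1:
        raise ValidationError("min_size must be >= 1")
    m_cap = math.inf
    if dispersion_cap is not None:
        if dispersion_cap <= 0:
            raise ValidationError("dispersion_cap must be positive")
        universe = shared_universe(matrices)
        m_cap = dispersion_cap * float(
            np.mean([cluster_mse(universe, m) for m in matrices])
        )
    survivors = [s for s in pool if len(s) >= min_size]
    elites: list[SeedCluster] = []
    while survivors:
        points = [
            p for p in mn_points(survivors, matrices, weight) if p.M <= m_cap
        ]
        if not points:
            break
        best = min(points, key=_tie_key)
        elites.append(best.seed)
        taken = best.seed.genes
        reduced: list[SeedCluster] = []
        for p in points:
            if p.seed is best.seed:
                continue
            remaining = p.seed.genes - taken
            if len(remaining) >= min_size:
                reduced.append(
                    p.seed
                    if remaining == p.seed.genes
                    else SeedCluster(remaining, source=p.seed.source)
                )
        survivors = reduced
    return elites
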