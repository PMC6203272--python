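"""Shared test helpers: matrix construction and brute-force oracles.

The oracles are deliberately naive re-derivations (pair counting,
explicit loops, algebraic identities) kept independent of the library
code paths they check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from clustex import ExpressionMatrix


def make_matrix(values, gene_ids=None, condition_ids=None, dataset_id="ds") -> ExpressionMatrix:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, d = values.shape
    gene_ids = list(gene_ids) if gene_ids is not None else [f"g{i}" for i in range(n)]
    condition_ids = (
        list(condition_ids) if condition_ids is not None else [f"c{j}" for j in range(d)]
    )
    return ExpressionMatrix(
        dataset_id, pd.DataFrame(values, index=gene_ids, columns=condition_ids)
    )


def set_partitions(items: list):
    """Yield every partition of ``items`` into non-empty blocks."""
    if not items:
        yield []
        return
    head, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [smaller[i] + [head]] + smaller[i + 1 :]
        yield smaller + [[head]]


def ari_pair_counting(labels_a, labels_b) -> float:
    """ARI from first principles: count agreeing/disagreeing item pairs."""
    n = len(labels_a)
    both = a_only = b_only = neither = 0
    for i, j in combinations(range(n), 2):
        same_a = labels_a[i] == labels_a[j]
        same_b = labels_b[i] == labels_b[j]
        if same_a and same_b:
            both += 1
        elif same_a:
            a_only += 1
        elif same_b:
            b_only += 1
        else:
            neither += 1
    total = both + a_only + b_only + neither
    expected = (both + a_only) * (both + b_only) / total
    maximum = 0.5 * ((both + a_only) + (both + b_only))
    if maximum == expected:
        return 1.0
    return (both - expected) / (maximum - expected)


def silhouette_brute(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette coefficient via explicit distance loops."""
    n = len(X)
    dist = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    scores = []
    for i in range(n):
        same = [j for j in range(n) if j != i and labels[j] == labels[i]]
        if not same:
            scores.append(0.0)
            continue
        a = float(np.mean([dist[i, j] for j in same]))
        b = min(
            float(np.mean([dist[i, j] for j in range(n) if labels[j] == lab]))
            for lab in set(labels)
            if lab != labels[i]
        )
        scores.append((b - a) / max(a, b))
    return float(np.mean(scores))


def mse_pairwise(X: np.ndarray) -> float:
    """Cluster MSE via the pairwise-distance identity.

    (1/(D N)) sum_g ||x_g - mean||^2 == (1/(2 D N^2)) sum_{g,h} ||x_g - x_h||^2,
    an algebraic identity independent of the mean-profile formulation.
    """
    n, d = X.shape
    total = ((X[:, None, :] - X[None, :, :]) ** 2).sum()
    return float(total / (2 * d * n * n))
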