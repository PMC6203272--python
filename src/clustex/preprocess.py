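"""Expression-matrix pre-processing.

The pipeline prepares each input dataset with the standard sequence for
co-expression analysis: quantile normalization, log transform, median
summarization of replicates, a low-expression filter, and finally per-gene
z-scores (or zero-centering for two-colour microarray data, whose values
are already log-ratios around zero).

Committed step order
--------------------
``quantile -> log2 -> summarize replicates -> low-expression filter ->
z-score | center``.  The low-expression filter must see values on the
summarized, pre-z-score scale: after z-scoring every gene has mean zero and
unit variance, so an abundance threshold would be meaningless.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_model import ExpressionMatrix, ReplicateMap, ValidationError

#: Recognized normalization codes.
CODES = ("quantile", "log2", "zscore", "center", "none")


@dataclass
class NormalizationPlan:
    """Ordered normalization codes for one dataset.

    ``codes`` is a subset of :data:`CODES`; the pipeline applies the steps
    it names in the committed order regardless of the order given.
    ``two_colour`` marks two-colour microarray data, for which centering
    substitutes for z-scoring.
    """

    codes: list[str] = field(default_factory=lambda: ["quantile", "log2", "zscore"])
    two_colour: bool = False

    def __post_init__(self) -> None:
        unknown = [c for c in self.codes if c not in CODES]
        if unknown:
            raise ValidationError(f"unknown normalization codes: {unknown}")
        if "zscore" in self.codes and "center" in self.codes:
            raise ValidationError("zscore and center are mutually exclusive")
        if self.codes.count("log2") > 1:
            raise ValidationError("log2 may appear at most once")

    @classmethod
    def parse(cls, spec: str, two_colour: bool = False) -> "NormalizationPlan":
        """Parse a comma-separated code string such as ``"quantile,log2,zscore"``."""
        codes = [c.strip() for c in spec.split(",") if c.strip()]
        if codes == ["none"]:
            codes = []
        return cls(codes=codes, two_colour=two_colour)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every column to the same empirical distribution.

    Each column's values are replaced by the across-column means of the
    order statistics at their rank; tied values receive the average of the
    rank means they span, so the transform is permutation-equivariant.
    """
    if m.n_genes == 0 or m.n_conditions == 0:
        raise ValidationError("cannot quantile-normalize an empty matrix")
    X = m.values
    rank_means = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    grid = np.arange(1, X.shape[0] + 1, dtype=float)
    for j in range(X.shape[1]):
        ranks = rankdata(X[:, j], method="average")  # fractional under ties
        out[:, j] = np.interp(ranks, grid, rank_means)
    return m.with_values(out, "quantile")


def log_transform(m: ExpressionMatrix, pseudo_count: float = 1.0) -> ExpressionMatrix:
    """Apply ``v -> log2(v + pseudo_count)`` to every value."""
    X = m.values
    if (X < 0).any():
        raise ValidationError(
            f"dataset {m.dataset_id!r} contains negative values; the data may "
            "already be on a log scale (drop the log2 code)"
        )
    return m.with_values(np.log2(X + pseudo_count), "log2")


def zscore_rows(m: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each gene row to mean 0, population standard deviation 1.

    Zero-variance rows cannot be standardized; they become all-zero and
    their gene ids are recorded under ``flags["zero_variance"]``.
    """
    if m.n_conditions < 2:
        raise ValidationError("z-scoring needs at least two conditions")
    X = m.values
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)  # population (divide-by-n)
    flat = sd[:, 0] == 0.0
    sd_safe = np.where(sd == 0.0, 1.0, sd)
    out = (X - mu) / sd_safe
    out[flat, :] = 0.0
    new = m.with_values(out, "zscore")
    if flat.any():
        new.flags["zero_variance"] = [g for g, f in zip(m.gene_ids, flat) if f]
    return new


def center_rows(m: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene row's mean; variance is left untouched."""
    X = m.values
    return m.with_values(X - X.mean(axis=1, keepdims=True), "center")


def summarize_replicates(m: ExpressionMatrix, rep: ReplicateMap | dict[str, list[str]]) -> ExpressionMatrix:
    """Collapse replicate sample columns to one median column per condition.

    ``rep`` may be a full :class:`ReplicateMap` (its entry for this
    dataset is used) or a plain condition -> samples mapping.  With no
    entry for the dataset the matrix is returned unchanged — every sample
    is treated as its own condition.
    """
    mapping = rep.for_dataset(m.dataset_id) if isinstance(rep, ReplicateMap) else rep
    if not mapping:
        return m
    missing = [
        s for samples in mapping.values() for s in samples if s not in m.data.columns
    ]
    if missing:
        raise ValidationError(
            f"replicate map names samples absent from dataset "
            f"{m.dataset_id!r}: {missing}"
        )
    cols = {cond: m.data[samples].median(axis=1) for cond, samples in mapping.items()}
    df = pd.DataFrame(cols, index=m.data.index)
    return m.with_values(df.to_numpy(), "summarize", columns=list(df.columns))


def filter_low_expression(m: ExpressionMatrix) -> tuple[ExpressionMatrix, set[str]]:
    """Drop genes that are never meaningfully expressed.

    A gene is retained iff its value strictly exceeds the flat 25th
    percentile of all matrix values at ``>= ceil(0.25 * D)`` of its ``D``
    conditions.  Returns the filtered matrix and the removed gene ids.
    Must run on the pre-z-score scale.
    """
    X = m.values
    threshold = float(np.percentile(X, 25))  # linear interpolation
    need = math.ceil(0.25 * m.n_conditions)
    keep = (X > threshold).sum(axis=1) >= need
    removed = {g for g, k in zip(m.gene_ids, keep) if not k}
    kept_ids = [g for g, k in zip(m.gene_ids, keep) if k]
    filtered = ExpressionMatrix(
        m.dataset_id, m.data.loc[kept_ids], m.trace + ["filter25"], dict(m.flags)
    )
    return filtered, removed


def preprocess(
    m: ExpressionMatrix,
    plan: NormalizationPlan | None = None,
    replicate_map: ReplicateMap | dict[str, list[str]] | None = None,
    filter_low: bool = True,
    pseudo_count: float = 1.0,
) -> ExpressionMatrix:
    """Run the committed pre-processing sequence on one dataset.

    Steps named in ``plan.codes`` are applied in the committed order
    (quantile, log2, summarize, filter, z-score/center); replicate
    summarization runs whenever a map covering this dataset is supplied and
    the low-expression filter whenever ``filter_low`` is true.  Removed
    genes are recorded under ``flags["filtered_low_expression"]``.
    """
    plan = plan or NormalizationPlan()
    codes = set(plan.codes)
    if "log2" in codes and m.n_genes and m.values.max() < 30:
        warnings.warn(
            f"dataset {m.dataset_id!r}: max value {m.values.max():.3g} < 30 — "
            "the data may already be log-scale; log2 will still be applied",
            stacklevel=2,
        )
    if "quantile" in codes:
        m = quantile_normalize(m)
    if "log2" in codes:
        m = log_transform(m, pseudo_count)
    if replicate_map is not None:
        m = summarize_replicates(m, replicate_map)
    if filter_low:
        m, removed = filter_low_expression(m)
        m.flags["filtered_low_expression"] = sorted(removed)
    if plan.two_colour or "center" in codes:
        m = center_rows(m)
    elif "zscore" in codes:
        m = zscore_rows(m)
    if m.n_genes == 0:
        raise ValidationError(
            f"dataset {m.dataset_id!r}: no genes survive pre-processing"
        )
    return m
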