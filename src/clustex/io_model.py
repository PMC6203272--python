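"""Core data containers and delimited-text I/O.

The central object is the :class:`ExpressionMatrix`: a genes x conditions
table of real values with a record ("trace") of the normalization steps that
produced it.  Clustering results are held as :class:`ClusterResult` — an
ordered list of pairwise-disjoint gene sets plus summary statistics — and
hard assignments from a single clustering run as :class:`Partition`.

All file formats are plain delimited text.  The delimiter is inferred from
the file extension (``.tsv`` -> tab, ``.csv`` -> comma) and can always be
overridden explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Sentinel label for genes not assigned to any cluster in a Partition.
UNASSIGNED = -1


class ValidationError(ValueError):
    """An object violates one of its structural invariants."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending cell."""


def _infer_delimiter(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    suffix = Path(path).suffix.lower()
    if suffix == ".csv":
        return ","
    return "\t"


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A genes x conditions expression table.

    Parameters
    ----------
    dataset_id:
        Free-text label for the dataset this matrix came from.
    data:
        DataFrame indexed by gene identifier with one column per condition.
        Values must be finite floats; gene identifiers must be unique and
        are compared case-sensitively as opaque strings.
    trace:
        Ordered list of normalization codes already applied (e.g.
        ``["quantile", "log2", "zscore"]``).
    flags:
        Free-form diagnostics recorded by processing steps, e.g. the set of
        zero-variance genes encountered during z-scoring.
    """

    dataset_id: str
    data: pd.DataFrame
    trace: list[str] = field(default_factory=list)
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(
                f"duplicate gene identifiers in dataset {self.dataset_id!r}: {dupes}"
            )
        self.data = self.data.astype(float)
        if not np.isfinite(self.data.to_numpy()).all():
            raise ValidationError(
                f"non-finite values in dataset {self.dataset_id!r}"
            )

    # -- accessors ----------------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def condition_ids(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_conditions(self) -> int:
        """Number of conditions; the dimensionality D of every gene profile."""
        return self.data.shape[1]

    # -- derivation helpers -------------------------------------------------

    def with_values(
        self,
        values: np.ndarray,
        step: str | None = None,
        columns: Sequence[str] | None = None,
    ) -> "ExpressionMatrix":
        """Return a copy carrying new values and an extended trace."""
        cols = list(columns) if columns is not None else list(self.data.columns)
        df = pd.DataFrame(np.asarray(values, dtype=float), index=self.data.index, columns=cols)
        trace = self.trace + ([step] if step else [])
        return ExpressionMatrix(self.dataset_id, df, trace, dict(self.flags))

    def subset(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        """Row-subset (and reorder) to the given gene identifiers."""
        ids = list(gene_ids)
        missing = [g for g in ids if g not in self.data.index]
        if missing:
            raise ValidationError(
                f"genes absent from dataset {self.dataset_id!r}: {missing[:5]}"
            )
        return ExpressionMatrix(
            self.dataset_id, self.data.loc[ids], list(self.trace), dict(self.flags)
        )

    def profiles(self, gene_ids: Iterable[str]) -> np.ndarray:
        """Profile matrix for the given genes, in the given order."""
        return self.subset(list(gene_ids)).values


def read_expression_matrix(
    path: str | Path,
    delimiter: str | None = None,
    dataset_id: str | None = None,
) -> ExpressionMatrix:
    """Read a delimited genes x samples matrix.

    The first column holds gene identifiers; the header row holds sample
    (condition) names.  Every remaining cell must parse as a finite number;
    the first malformed cell is reported by gene and column name.
    """
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if raw.shape[1] == 0:
        raise ValidationError(f"{path}: no sample columns found")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = ~np.isfinite(numeric.to_numpy())
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: cell ({raw.index[i]!r}, {raw.columns[j]!r}) = "
            f"{raw.iloc[i, j]!r} is not a finite number"
        )
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate gene identifiers {dupes}")
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    return ExpressionMatrix(dataset_id or path.stem, numeric)


def write_expression_matrix(
    m: ExpressionMatrix, path: str | Path, delimiter: str | None = None
) -> None:
    sep = _infer_delimiter(path, delimiter)
    m.data.to_csv(path, sep=sep, index_label="Gene")


# ---------------------------------------------------------------------------
# ReplicateMap
# ---------------------------------------------------------------------------


@dataclass
class ReplicateMap:
    """Maps dataset -> condition -> list of replicate sample columns.

    Each sample column may appear under at most one condition of its
    dataset; replicate summarization collapses the listed columns to their
    per-gene median.
    """

    entries: dict[str, dict[str, list[str]]]

    def __post_init__(self) -> None:
        for ds, conds in self.entries.items():
            seen: dict[str, str] = {}
            for cond, samples in conds.items():
                if not samples:
                    raise ValidationError(
                        f"condition {cond!r} of dataset {ds!r} lists no samples"
                    )
                for s in samples:
                    if s in seen:
                        raise ValidationError(
                            f"sample {s!r} of dataset {ds!r} appears under both "
                            f"{seen[s]!r} and {cond!r}"
                        )
                    seen[s] = cond

    def for_dataset(self, dataset_id: str) -> dict[str, list[str]] | None:
        return self.entries.get(dataset_id)


def read_replicate_map(path: str | Path, delimiter: str | None = None) -> ReplicateMap:
    """Read a 3-column (dataset, condition, sample) delimited file."""
    sep = _infer_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.shape[1] < 3:
        raise ParseError(f"{path}: replicate map needs 3 columns, found {df.shape[1]}")
    entries: dict[str, dict[str, list[str]]] = {}
    for ds, cond, sample in df.iloc[:, :3].itertuples(index=False):
        entries.setdefault(str(ds), {}).setdefault(str(cond), []).append(str(sample))
    return ReplicateMap(entries)


# ---------------------------------------------------------------------------
# Partition
# ---------------------------------------------------------------------------


@dataclass
class Partition:
    """Hard assignment of genes to clusters ``0..K-1``.

    Genes carrying :data:`UNASSIGNED` belong to no cluster (cluster
    *extraction* results, unlike partitioning methods, need not cover the
    whole gene universe).
    """

    labels: dict[str, int]
    K: int

    def __post_init__(self) -> None:
        for g, lab in self.labels.items():
            if lab != UNASSIGNED and not (0 <= lab < self.K):
                raise ValidationError(f"gene {g!r} has label {lab} outside 0..{self.K - 1}")

    @property
    def genes(self) -> set[str]:
        return set(self.labels)

    def clusters(self) -> list[set[str]]:
        """Cluster gene sets, indexed by label; unassigned genes excluded."""
        out: list[set[str]] = [set() for _ in range(self.K)]
        for g, lab in self.labels.items():
            if lab != UNASSIGNED:
                out[lab].add(g)
        return out

    @classmethod
    def from_clusters(cls, clusters: Sequence[Iterable[str]], universe: Iterable[str] | None = None) -> "Partition":
        labels: dict[str, int] = {}
        for k, genes in enumerate(clusters):
            for g in genes:
                labels[g] = k
        if universe is not None:
            for g in universe:
                labels.setdefault(g, UNASSIGNED)
        return cls(labels, K=len(clusters))


# ---------------------------------------------------------------------------
# ClusterResult
# ---------------------------------------------------------------------------


@dataclass
class ClusterResult:
    """Final disjoint clusters plus summary metrics.

    ``clusters`` holds one sorted gene-id tuple per cluster; empty clusters
    are never stored.  The metric fields may be ``None`` for results read
    back from disk (only gene sets round-trip through the cluster file).

    ``pag`` is the percentage of the retained gene universe assigned to any
    cluster, in [0, 100].
    """

    clusters: list[tuple[str, ...]]
    n_retained: int | None = None
    per_cluster_mse: list[float] | None = None
    overall_mse: float | None = None
    ji: float | None = None
    pag: float | None = None

    def __post_init__(self) -> None:
        self.clusters = [tuple(sorted(c)) for c in self.clusters]
        seen: set[str] = set()
        for k, c in enumerate(self.clusters):
            if not c:
                raise ValidationError(f"cluster {k} is empty")
            overlap = seen.intersection(c)
            if overlap:
                raise ValidationError(
                    f"clusters are not disjoint: {sorted(overlap)[:5]} appear twice"
                )
            seen.update(c)
        if self.pag is not None and not (0.0 <= self.pag <= 100.0 + 1e-9):
            raise ValidationError(f"PAG {self.pag} outside [0, 100]")

    @property
    def K(self) -> int:
        return len(self.clusters)

    @property
    def n_assigned(self) -> int:
        return sum(len(c) for c in self.clusters)

    @property
    def assigned_genes(self) -> set[str]:
        return {g for c in self.clusters for g in c}

    def gene_sets(self) -> list[set[str]]:
        return [set(c) for c in self.clusters]

    def to_partition(self, universe: Iterable[str] | None = None) -> Partition:
        return Partition.from_clusters(self.clusters, universe)


def write_cluster_result(result: ClusterResult, path: str | Path, delimiter: str | None = None) -> None:
    """Write clusters as a wide table: one column per cluster.

    Column headers are ``C0 (n0)``, ``C1 (n1)``, ... with member gene ids
    listed beneath; shorter columns are padded with empty cells.  A result
    with no clusters yields a file with an empty header line.
    """
    sep = _infer_delimiter(path, delimiter)
    headers = [f"C{k} ({len(c)})" for k, c in enumerate(result.clusters)]
    depth = max((len(c) for c in result.clusters), default=0)
    with open(path, "w") as fh:
        fh.write(sep.join(headers) + "\n")
        for i in range(depth):
            row = [c[i] if i < len(c) else "" for c in result.clusters]
            fh.write(sep.join(row) + "\n")


def read_cluster_result(path: str | Path, delimiter: str | None = None) -> ClusterResult:
    """Read a wide cluster table written by :func:`write_cluster_result`."""
    sep = _infer_delimiter(path, delimiter)
    with open(path) as fh:
        lines = [line.rstrip("\n") for line in fh]
    if not lines or lines[0] == "":
        return ClusterResult(clusters=[])
    headers = lines[0].split(sep)
    cols: list[list[str]] = [[] for _ in headers]
    for line in lines[1:]:
        for j, cell in enumerate(line.split(sep)):
            if j < len(cols) and cell != "":
                cols[j].append(cell)
    return ClusterResult(clusters=[tuple(sorted(c)) for c in cols if c])


def write_cluster_summary(result: ClusterResult, path: str | Path, delimiter: str | None = None) -> None:
    """Write a per-cluster summary table (cluster, size, MSE)."""
    sep = _infer_delimiter(path, delimiter)
    mses = result.per_cluster_mse or [math.nan] * result.K
    with open(path, "w") as fh:
        fh.write(sep.join(["cluster", "size", "MSE"]) + "\n")
        for k, c in enumerate(result.clusters):
            fh.write(sep.join([f"C{k}", str(len(c)), f"{mses[k]:.6g}"]) + "\n")
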