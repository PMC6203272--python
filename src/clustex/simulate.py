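"""Synthetic time-course expression data with planted co-expression clusters.

The generator emulates a standard benchmark design for cluster-extraction
methods: 500 genes over six time-points, of which 300 form three planted
clusters of 100 genes (mean profiles: monotone up, monotone down, and
up-then-down) and 200 are "unclustered" — random profiles guaranteed not
to fit inside any planted cluster's profile band.  Member profiles are the
cluster mean plus i.i.d. Gaussian noise of standard deviation σ; the
canonical series uses σ ∈ {0, 0.4, 0.8, 1.2}.  The final matrix is
z-scored per gene, as the benchmark datasets are.

Everything is deterministic given the config seed; the same seed with a
different σ yields the same truth labels (the design fixes them).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_model import ExpressionMatrix, ValidationError

#: Noise levels of the canonical four-dataset series D1..D4.
DEFAULT_SIGMAS = (0.0, 0.4, 0.8, 1.2)

#: Truth label for genes belonging to no planted cluster.
UNCLUSTERED = 0

#: Outward padding of the exclusion boxes, so that exclusion remains
#: meaningful at σ = 0 (a zero-width box would exclude nothing) and every
#: accepted gene clears a planted cluster's box by a strict margin.
_BAND_PAD = 0.25


@dataclass
class SimulationConfig:
    """Design parameters of one simulated dataset.

    The defaults reproduce the canonical design: 3 x 100 clustered genes
    plus 200 unclustered over 6 time-points.  ``sigma`` is the std of the
    Gaussian noise added to the cluster mean profiles (on the raw profile
    scale, whose ramps span −1.25..+1.25).
    """

    n_per_cluster: int = 100
    n_unclustered: int = 200
    n_timepoints: int = 6
    sigma: float = 0.0
    seed: int = 0
    max_rejections: int = 10_000

    def __post_init__(self) -> None:
        if self.n_per_cluster < 1 or self.n_unclustered < 0:
            raise ValidationError("gene counts must be positive")
        if self.n_timepoints < 2:
            raise ValidationError("need at least two time-points")
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")

    @property
    def n_genes(self) -> int:
        return 3 * self.n_per_cluster + self.n_unclustered


@dataclass
class SimulatedDataset:
    """A simulated matrix together with its ground truth.

    ``matrix`` is z-scored per gene; ``raw`` holds the pre-z-score values
    (cluster mean + noise; standard-normal draws for unclustered genes).
    ``truth`` maps every gene id to 1, 2 or 3 (planted cluster) or
    :data:`UNCLUSTERED`.
    """

    matrix: ExpressionMatrix
    raw: ExpressionMatrix
    truth: dict[str, int]
    config: SimulationConfig = field(repr=False, default=None)  # type: ignore[assignment]

    def truth_clusters(self) -> list[set[str]]:
        """The three planted gene sets, in cluster order."""
        return [
            {g for g, lab in self.truth.items() if lab == k} for k in (1, 2, 3)
        ]

    @property
    def unclustered_genes(self) -> set[str]:
        return {g for g, lab in self.truth.items() if lab == UNCLUSTERED}


def base_profiles(n_timepoints: int) -> np.ndarray:
    """Mean profiles of the three planted clusters (3 x T).

    Cluster 1 rises linearly from −1.25 to +1.25, cluster 2 is its
    mirror image, and cluster 3 is a symmetric tent peaking mid-course.
    """
    up = np.linspace(-1.25, 1.25, n_timepoints)
    half = (n_timepoints + 1) // 2
    ramp = np.linspace(-1.25, 1.25, half)
    tent = np.concatenate([ramp, ramp[::-1]])[
        : n_timepoints
    ] if n_timepoints % 2 == 0 else np.concatenate([ramp, ramp[-2::-1]])
    return np.stack([up, -up, tent])


def _zscore(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (X - mu) / sd


def generate(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate one simulated dataset.

    Cluster members are the mean profile plus N(0, σ²) noise per point.
    Unclustered genes are standard-normal profiles rejection-sampled (in
    the z-scored space everything is measured in) until they fall outside
    every planted cluster's trimmed boundary box — the per-point 1st..99th
    percentile interval of the cluster's z-scored members, padded outward
    by 0.25 — at one point or more.  Rejecting against the boxes makes the
    design guarantee exact: no unclustered gene can ever be an overlap
    gene with respect to a planted cluster.  Raises if a single gene
    exhausts ``cfg.max_rejections`` draws, which indicates the exclusion
    boxes cover essentially all profile space.
    """
    rng = np.random.default_rng(cfg.seed)
    T = cfg.n_timepoints
    means = base_profiles(T)

    member_raw = np.concatenate(
        [
            means[k] + rng.normal(0.0, cfg.sigma, size=(cfg.n_per_cluster, T))
            for k in range(3)
        ]
    )
    member_z = _zscore(member_raw)
    # padded per-point boundary boxes of the z-scored members: exclusion zones
    bands = []
    for k in range(3):
        Z = member_z[k * cfg.n_per_cluster : (k + 1) * cfg.n_per_cluster]
        lo, hi = np.percentile(Z, 1, axis=0), np.percentile(Z, 99, axis=0)
        bands.append((lo - _BAND_PAD, hi + _BAND_PAD))

    unclust_raw = np.empty((cfg.n_unclustered, T))
    for i in range(cfg.n_unclustered):
        for attempt in range(cfg.max_rejections):
            x = rng.normal(0.0, 1.0, size=T)
            xz = _zscore(x[None, :])[0]
            inside_any = any(
                bool(((xz >= lo) & (xz <= hi)).all()) for lo, hi in bands
            )
            if not inside_any:
                unclust_raw[i] = x
                break
        else:
            raise ValidationError(
                "rejection sampling for unclustered genes exhausted "
                f"{cfg.max_rejections} draws; widen sigma or loosen the exclusion band"
            )

    raw = np.concatenate([member_raw, unclust_raw])
    gene_ids = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    truth = {
        g: (i // cfg.n_per_cluster + 1 if i < 3 * cfg.n_per_cluster else UNCLUSTERED)
        for i, g in enumerate(gene_ids)
    }
    cols = [f"T{t + 1}" for t in range(T)]
    raw_m = ExpressionMatrix("sim", pd.DataFrame(raw, index=gene_ids, columns=cols))
    z_m = ExpressionMatrix(
        "sim",
        pd.DataFrame(_zscore(raw), index=gene_ids, columns=cols),
        trace=["zscore"],
    )
    return SimulatedDataset(matrix=z_m, raw=raw_m, truth=truth, config=cfg)


def generate_series(
    sigmas: Sequence[float] = DEFAULT_SIGMAS,
    seed: int = 0,
    **kwargs,
) -> list[SimulatedDataset]:
    """Generate the canonical noise series D1..Dn (default σ = 0..1.2).

    All datasets share the same seed and hence the same design and truth
    labels; only the noise level varies.
    """
    if not sigmas:
        raise ValidationError("need at least one sigma value")
    base = SimulationConfig(seed=seed, **kwargs)
    out = []
    for ds_index, s in enumerate(sigmas):
        cfg = replace(base, sigma=float(s), seed=_series_seed(seed, ds_index))
        out.append(generate(cfg))
    return out


def _series_seed(seed: int, ds_index: int) -> int:
    """Independent noise per dataset in a series, reproducible from one seed."""
    return (seed * 1_000_003 + ds_index * 97 + 11) % (2**31)


def write_simulated(ds: SimulatedDataset, out_dir: str | Path, stem: str = "sim") -> tuple[Path, Path]:
    """Write the z-scored matrix and a 2-column truth TSV; returns both paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mat_path = out_dir / f"{stem}_expression.tsv"
    truth_path = out_dir / f"{stem}_truth.tsv"
    ds.matrix.data.to_csv(mat_path, sep="\t", index_label="Gene")
    with open(truth_path, "w") as fh:
        fh.write("Gene\tcluster\n")
        for g in ds.matrix.gene_ids:
            fh.write(f"{g}\t{ds.truth[g]}\n")
    return mat_path, truth_path
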