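"""End-to-end orchestration: pre-process, seed, select, refine, report.

The library entry point is :func:`extract_clusters`, which runs the four
pipeline stages on already-pre-processed matrices.  :func:`run` wraps it
with file I/O: it loads the datasets, applies each dataset's normalization
plan, executes the pipeline, and writes the cluster file, the per-cluster
summary, the unclustered-gene list, the processed matrices, and a YAML log
recording every parameter and per-stage pool size (seeds -> elites ->
final K), which together fully determine the outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import refine as refine_mod
from .io_model import (
    ClusterResult,
    ExpressionMatrix,
    Partition,
    ReplicateMap,
    ValidationError,
    read_expression_matrix,
    read_replicate_map,
    write_cluster_result,
    write_cluster_summary,
    write_expression_matrix,
)
from .metrics import adjusted_rand_index
from .preprocess import NormalizationPlan, preprocess
from .refine import DEFAULT_MAX_ITER, DEFAULT_TIGHTNESS
from .seeds import SeedConfig, kmeans_pool, multi_dataset_seed_pool, shared_universe
from .selection import DEFAULT_DISPERSION_CAP, DEFAULT_MIN_SIZE, select_elites

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; fully determines its outputs."""

    data_paths: list[str]
    normalization: list[str] = field(default_factory=list)  # one code string per dataset
    replicate_map_path: str | None = None
    filter_low: bool = True
    seed_config: SeedConfig = field(default_factory=SeedConfig)
    min_size: int = DEFAULT_MIN_SIZE
    mn_weight: float = 1.0
    dispersion_cap: float | None = DEFAULT_DISPERSION_CAP
    tightness: float = DEFAULT_TIGHTNESS
    max_iter: int = DEFAULT_MAX_ITER
    out_dir: str = "clustex_out"

    def __post_init__(self) -> None:
        if not self.data_paths:
            raise ValidationError("at least one dataset is required")
        if self.normalization and len(self.normalization) not in (1, len(self.data_paths)):
            raise ValidationError(
                "give one normalization code string, or one per dataset"
            )


def extract_clusters(
    matrices: Sequence[ExpressionMatrix],
    seed_config: SeedConfig | None = None,
    min_size: int = DEFAULT_MIN_SIZE,
    mn_weight: float = 1.0,
    dispersion_cap: float | None = DEFAULT_DISPERSION_CAP,
    tightness: float = DEFAULT_TIGHTNESS,
    max_iter: int = DEFAULT_MAX_ITER,
    stats: dict | None = None,
) -> ClusterResult:
    """Run seed generation, elite selection and refinement on processed data.

    Matrices must already be pre-processed (z-scored or centered).  With
    one dataset the seed pool comes from repeated k-means alone; with
    several, from the Bi-CoPaM consensus over the shared gene universe.
    The returned result always has JI = 0; it may legitimately contain
    zero clusters when no consistent co-expression survives refinement.
    If ``stats`` is given, the per-stage pool sizes (seeds -> elites ->
    final K) are recorded in it.
    """
    cfg = seed_config or SeedConfig()
    if len(matrices) == 1:
        pool = kmeans_pool(matrices[0], cfg)
        universe = matrices[0].gene_ids
    else:
        pool = multi_dataset_seed_pool(matrices, cfg)
        universe = shared_universe(matrices)
    elites = select_elites(
        pool, matrices, min_size=min_size, weight=mn_weight, dispersion_cap=dispersion_cap
    )
    logger.info(
        "pipeline funnel: %d seeds -> %d elites", len(pool), len(elites)
    )
    result = refine_mod.refine(
        elites,
        matrices,
        q=tightness,
        max_iter=max_iter,
        min_size=min_size,
        universe=universe,
    )
    logger.info("final result: K=%d, PAG=%.1f%%", result.K, result.pag or 0.0)
    if stats is not None:
        stats.update(seeds=len(pool), elites=len(elites), K=result.K)
    return result


def run(cfg: RunConfig) -> ClusterResult:
    """Load, pre-process, cluster, and write all output files."""
    rep = read_replicate_map(cfg.replicate_map_path) if cfg.replicate_map_path else None
    plans = cfg.normalization or ["quantile,log2,zscore"]
    if len(plans) == 1:
        plans = plans * len(cfg.data_paths)
    matrices: list[ExpressionMatrix] = []
    for path, plan_spec in zip(cfg.data_paths, plans):
        m = read_expression_matrix(path)
        m = preprocess(
            m,
            NormalizationPlan.parse(plan_spec),
            replicate_map=rep,
            filter_low=cfg.filter_low,
        )
        matrices.append(m)

    funnel: dict = {}
    result = extract_clusters(
        matrices,
        seed_config=cfg.seed_config,
        min_size=cfg.min_size,
        mn_weight=cfg.mn_weight,
        dispersion_cap=cfg.dispersion_cap,
        tightness=cfg.tightness,
        max_iter=cfg.max_iter,
        stats=funnel,
    )

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_cluster_result(result, out / "clusters.tsv")
    write_cluster_summary(result, out / "cluster_summary.tsv")
    for m in matrices:
        write_expression_matrix(m, out / f"processed_{m.dataset_id}.tsv")
    universe = matrices[0].gene_ids if len(matrices) == 1 else shared_universe(matrices)
    unassigned = [g for g in universe if g not in result.assigned_genes]
    (out / "unclustered.txt").write_text("\n".join(unassigned) + ("\n" if unassigned else ""))
    log = {
        "data": list(cfg.data_paths),
        "normalization": plans,
        "replicate_map": cfg.replicate_map_path,
        "filter_low_expression": cfg.filter_low,
        "k_grid": list(cfg.seed_config.k_grid),
        "restarts": cfg.seed_config.restarts,
        "delta_grid": list(cfg.seed_config.delta_grid),
        "seed": cfg.seed_config.seed,
        "min_cluster_size": cfg.min_size,
        "mn_weight": cfg.mn_weight,
        "dispersion_cap": cfg.dispersion_cap,
        "tightness": cfg.tightness,
        "max_iterations": cfg.max_iter,
        "funnel": funnel,
        "K": result.K,
        "PAG": result.pag,
        "MSE": result.overall_mse,
        "JI": result.ji,
    }
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=False)
    return result


def compare_partitions(partitions: Sequence[Partition]) -> np.ndarray:
    """Pairwise ARI matrix between clustering results on one gene universe.

    Symmetric with unit diagonal; raises when the universes differ.
    """
    if len(partitions) < 2:
        raise ValidationError("need at least two results to compare")
    n = len(partitions)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = adjusted_rand_index(partitions[i], partitions[j])
    return out
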