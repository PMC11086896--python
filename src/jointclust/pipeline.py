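"""Per-problem recipes and the end-to-end pipeline.

Each benchmark problem fixes a feature transformation, a similarity norm,
and an association statistic:

* distributions — 10-bin histogram features, L2 similarity, KS-p association
* correlated    — ECDF features on a 100-point grid, L2 similarity,
                  Spearman-|rho| association
* two_gene      — min-max normalized moment time-courses, L2 similarity,
                  Granger-p association (lag 1, either direction)

``run_pipeline`` chains simulate -> features -> distances -> assemble ->
qEE -> cluster -> evaluate as configured and writes every artifact in
plain machine-readable formats.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import io as jio
from .cluster import (
    NONMETRIC_METHODS,
    cluster_embedding,
    cluster_nonmetric,
    distances_as_features_baseline,
)
from .datasets import (
    LabeledDatasetPair,
    generate_correlated_data,
    generate_distribution_data,
    generate_two_gene_data,
)
from .distances import (
    DistanceTriplet,
    assemble,
    granger_association,
    ks_association,
    pairwise_norm_distance,
    spearman_association,
)
from .evaluate import TRUE_K, score_result
from .features import ecdf_features, histogram_features, minmax_timecourse
from .embedding import qee_transform

logger = logging.getLogger("jointclust")

__all__ = [
    "generate_problem",
    "triplet_for_problem",
    "assembled_for_problem",
    "run_pipeline",
]


def generate_problem(
    problem: str, seed: int, size_mode: str = "fixed", **options
) -> LabeledDatasetPair:
    if problem == "distributions":
        return generate_distribution_data(seed=seed, size_mode=size_mode, **options)
    if problem == "correlated":
        return generate_correlated_data(seed=seed, size_mode=size_mode, **options)
    if problem == "two_gene":
        return generate_two_gene_data(seed=seed, size_mode=size_mode, **options)
    raise ValueError(f"unknown problem {problem!r}")


def triplet_for_problem(
    pair: LabeledDatasetPair,
    n_bins: int = 10,
    grid_size: int = 100,
    eps: float = 1e-9,
    lag: int = 1,
    norm_p: float = 2.0,
    scale_factors: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> DistanceTriplet:
    """Build the problem's distance triplet from its dataset pair."""
    tag = pair.problem_tag
    if tag == "distributions":
        fx = histogram_features(pair.X_items, n_bins)
        fy = histogram_features(pair.Y_items, n_bins)
        dXY = ks_association(pair.X_items, pair.Y_items, eps)
    elif tag == "correlated":
        pooled = list(pair.X_items) + list(pair.Y_items)
        fx = ecdf_features(pooled, grid_size)
        fy_vals = fx.values[pair.m :]
        fx.values = fx.values[: pair.m]
        from .features import FeatureMatrix

        fy = FeatureMatrix(fy_vals, "ecdf")
        dXY = spearman_association(pair.X_items, pair.Y_items, eps)
    elif tag == "two_gene":
        fx = minmax_timecourse(pair.X_items)
        fy = minmax_timecourse(pair.Y_items)
        dXY = granger_association(pair.X_items, pair.Y_items, eps, lag)
    else:
        raise ValueError(f"unknown problem tag {tag!r}")
    is_euclidean = norm_p == 2.0
    return DistanceTriplet(
        dX=pairwise_norm_distance(fx, norm_p),
        dY=pairwise_norm_distance(fy, norm_p),
        dXY=dXY,
        dX_is_euclidean=is_euclidean,
        dY_is_euclidean=is_euclidean,
        scale_factors=scale_factors,
    )


def assembled_for_problem(
    pair: LabeledDatasetPair, **options
) -> tuple[DistanceTriplet, np.ndarray]:
    triplet = triplet_for_problem(pair, **options)
    return triplet, assemble(triplet)


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Run the configured pipeline end to end; returns the metrics dict.

    Writes (under ``out_dir``): the dataset and labels CSVs, the assembled
    matrix, the joint Euclidean distance, the embedding constants JSON,
    the coordinates CSV, the predicted labels CSV, and metrics.json.
    """
    from .config import PipelineConfig

    cfg = config if isinstance(config, PipelineConfig) else PipelineConfig(**config)
    out = Path(out_dir) if out_dir is not None else Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    t0 = time.time()
    pair = generate_problem(
        cfg.problem, seed=cfg.seed, size_mode=cfg.size_mode, **cfg.problem_options
    )
    logger.info("simulate: %s m=%d n=%d (%.2fs)", cfg.problem, pair.m, pair.n, time.time() - t0)
    jio.write_dataset(out, pair)

    t0 = time.time()
    triplet = triplet_for_problem(pair, **cfg.distance_options)
    D = assemble(triplet)
    ids = [f"X:{i}" for i in range(pair.m)] + [f"Y:{j}" for j in range(pair.n)]
    jio.write_matrix(out / "assembled_distance.csv", D, ids)
    logger.info("assemble: %dx%d (%.2fs)", *D.shape, time.time() - t0)

    k = cfg.k or TRUE_K[cfg.problem]
    method = cfg.method
    metrics: dict = {"problem": cfg.problem, "method": method, "k": k, "seed": cfg.seed}

    if method in ("ward", "kmeans", "qee_ward", "qee_kmeans"):
        t0 = time.time()
        joint, coords = qee_transform(triplet, **cfg.qee_options)
        c = joint.constants
        jio.write_matrix(out / "joint_distance.csv", joint.lambda_matrix, joint.item_ids)
        jio.write_matrix(
            out / "coordinates.csv",
            coords.coords,
            coords.item_ids,
            columns=[f"dim{i}" for i in range(coords.coords.shape[1])],
        )
        constants = {
            "c1": c.c1,
            "c2": c.c2,
            "c3": c.c3,
            "zeta": c.zeta,
            "anchor": c.anchor,
            "iterations_used": c.iterations_used,
            "schoenberg_min_eigenvalue": c.schoenberg_min_eigenvalue,
        }
        (out / "constants.json").write_text(json.dumps(constants, indent=2, sort_keys=True))
        logger.info(
            "embed: %d iterations, c3*zeta=%.4g, min eig=%.3g (%.2fs)",
            c.iterations_used, c.shift, c.schoenberg_min_eigenvalue, time.time() - t0,
        )
        res = cluster_embedding(coords, k, method.replace("qee_", ""), seed=cfg.seed)
        metrics["constants"] = constants
    elif method in NONMETRIC_METHODS:
        res = cluster_nonmetric(D, k, method, seed=cfg.seed)
    elif method in ("rows_ward", "rows_kmeans"):
        res = distances_as_features_baseline(D, k, method.replace("rows_", ""), seed=cfg.seed)
    else:
        raise ValueError(f"unknown method {method!r}")

    jio.write_predicted_labels(out / "predicted_labels.csv", ids, res.predicted_labels)
    score, components = score_result(pair, res.predicted_labels)
    metrics["ari_bar"] = score
    metrics.update(components)
    (out / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    logger.info("evaluate: composite ARI = %.4f", score)
    return metrics
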