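"""Benchmark evaluation: composite adjusted Rand index and replicated runs.

The composite score averages three adjusted Rand indices: agreement on X,
agreement on Y, and agreement between the true and predicted *pairing*
partitions, in which each paired unit (one X item + one Y item sharing a
pairing id) is assigned to a block keyed by the ordered pair of its
members' cluster labels.  The third term rewards co-clustering of truly
paired items across the two datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mannwhitneyu, rankdata, tiecorrect
from sklearn.metrics import adjusted_rand_score

__all__ = [
    "PartitionPair",
    "BenchmarkResult",
    "ari",
    "ari_bar",
    "run_benchmark",
    "compare_methods",
]


def ari(truth: np.ndarray, prediction: np.ndarray) -> float:
    """Adjusted Rand index between two labelings of the same items."""
    truth = np.asarray(truth)
    prediction = np.asarray(prediction)
    if truth.shape != prediction.shape:
        raise ValueError("label arrays must have equal length")
    if truth.size < 2:
        raise ValueError("need at least 2 items")
    return float(adjusted_rand_score(truth, prediction))


@dataclass
class PartitionPair:
    true_labels_X: np.ndarray
    predicted_X: np.ndarray
    true_labels_Y: np.ndarray
    predicted_Y: np.ndarray
    pairing_ids_X: np.ndarray
    pairing_ids_Y: np.ndarray

    def __post_init__(self) -> None:
        if len(self.true_labels_X) != len(self.predicted_X):
            raise ValueError("X arrays must have equal length")
        if len(self.true_labels_Y) != len(self.predicted_Y):
            raise ValueError("Y arrays must have equal length")
        if len(self.pairing_ids_X) != len(self.true_labels_X) or len(
            self.pairing_ids_Y
        ) != len(self.true_labels_Y):
            raise ValueError("pairing ids must align with the label arrays")


def _pairing_partition(
    labels_X: np.ndarray,
    labels_Y: np.ndarray,
    pid_X: np.ndarray,
    pid_Y: np.ndarray,
) -> np.ndarray:
    """Label each pair unit by the ordered (X label, Y label) pair."""
    pos_y = {int(p): i for i, p in enumerate(pid_Y)}
    keys = []
    for i, p in enumerate(pid_X):
        j = pos_y.get(int(p))
        if j is None:
            raise ValueError(f"pairing id {p} missing from Y")
        keys.append((int(labels_X[i]), int(labels_Y[j])))
    uniq = {key: c for c, key in enumerate(dict.fromkeys(keys))}
    return np.array([uniq[key] for key in keys])


def ari_bar(pp: PartitionPair) -> tuple[float, dict]:
    """Composite ARI: mean of the X, Y, and pairing-partition ARIs.

    Returns the score and the three components.
    """
    a_x = ari(pp.true_labels_X, pp.predicted_X)
    a_y = ari(pp.true_labels_Y, pp.predicted_Y)
    truth_pairs = _pairing_partition(
        pp.true_labels_X, pp.true_labels_Y, pp.pairing_ids_X, pp.pairing_ids_Y
    )
    pred_pairs = _pairing_partition(
        pp.predicted_X, pp.predicted_Y, pp.pairing_ids_X, pp.pairing_ids_Y
    )
    a_pair = ari(truth_pairs, pred_pairs)
    score = float(np.mean([a_x, a_y, a_pair]))
    return score, {"ari_X": a_x, "ari_Y": a_y, "ari_pairing": a_pair}


def score_result(pair, labels: np.ndarray) -> tuple[float, dict]:
    """Composite ARI of predicted labels (X block first) for a dataset pair."""
    m = pair.m
    pp = PartitionPair(
        pair.true_labels_X,
        labels[:m],
        pair.true_labels_Y,
        labels[m:],
        pair.pairing_ids_X,
        pair.pairing_ids_Y,
    )
    return ari_bar(pp)


@dataclass
class BenchmarkResult:
    problem_tag: str
    scores: dict[str, np.ndarray]  # method -> per-replicate composite ARI
    n_replicates: int
    size_mode: str
    seed: int
    summary: dict[str, dict] = field(default_factory=dict)
    comparisons: dict[str, dict] = field(default_factory=dict)

    def summarize(self) -> None:
        self.summary = {}
        for method, s in self.scores.items():
            s = np.asarray(s, dtype=float)
            self.summary[method] = {
                "median": float(np.median(s)),
                "iqr": [float(np.percentile(s, 25)), float(np.percentile(s, 75))],
                "p5_p95": [float(np.percentile(s, 5)), float(np.percentile(s, 95))],
                "mean": float(s.mean()),
            }

    def to_dict(self) -> dict:
        return {
            "problem": self.problem_tag,
            "n_replicates": self.n_replicates,
            "size_mode": self.size_mode,
            "seed": self.seed,
            "scores": {k: np.asarray(v).tolist() for k, v in self.scores.items()},
            "summary": self.summary,
            "comparisons": self.comparisons,
        }


def compare_methods(
    result: BenchmarkResult, method_a: str, method_b: str
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U between two methods' score arrays, with
    effect size r = |Z| / sqrt(n_a + n_b) (tie-corrected normal Z)."""
    a = np.asarray(result.scores[method_a], dtype=float)
    b = np.asarray(result.scores[method_b], dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 scores per method")
    n1, n2 = a.size, b.size
    combined = np.concatenate([a, b])
    tc = tiecorrect(rankdata(combined))
    if tc == 0:  # all values identical
        return 1.0, 0.0
    res = mannwhitneyu(a, b, alternative="two-sided")
    mu = n1 * n2 / 2.0
    sigma = np.sqrt(tc * n1 * n2 * (n1 + n2 + 1) / 12.0)
    z = (res.statistic - mu) / sigma
    r = abs(z) / np.sqrt(n1 + n2)
    return float(res.pvalue), float(r)


TRUE_K = {"distributions": 4, "correlated": 10, "two_gene": 4}

EUCLIDEAN_METHODS = {"qee_ward": "ward", "qee_kmeans": "kmeans"}
ROWS_METHODS = {"rows_ward": "ward", "rows_kmeans": "kmeans"}


def run_benchmark(
    problem: str,
    methods: list[str],
    n_replicates: int = 100,
    size_mode: str = "fixed",
    seed: int = 0,
    qee_options: dict | None = None,
    problem_options: dict | None = None,
) -> BenchmarkResult:
    """Replicated benchmark: fresh dataset per replicate, distance assembly,
    qEE for the Euclidean methods, raw assembled matrix for the non-metric
    baselines, clustering at the true k, composite-ARI scoring.

    ``methods`` mixes tags: 'qee_ward'/'qee_kmeans' (embedding), the
    non-metric tags ('kmedoids', 'spectral', 'complete', 'average',
    'single'), and 'rows_ward'/'rows_kmeans' (distance rows as features).
    """
    from .pipeline import assembled_for_problem, generate_problem

    if problem not in TRUE_K:
        raise ValueError(f"unknown problem {problem!r}")
    from .cluster import NONMETRIC_METHODS

    for mth in methods:
        if (
            mth not in EUCLIDEAN_METHODS
            and mth not in ROWS_METHODS
            and mth not in NONMETRIC_METHODS
        ):
            raise ValueError(f"unknown method tag {mth!r}")

    qee_options = dict(qee_options or {})
    problem_options = dict(problem_options or {})
    k = TRUE_K[problem]
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_replicates)]

    from .cluster import (
        cluster_embedding,
        cluster_nonmetric,
        distances_as_features_baseline,
    )
    from .embedding import qee_transform

    scores: dict[str, list[float]] = {mth: [] for mth in methods}
    for rep_seed in child_seeds:
        pair = generate_problem(problem, seed=rep_seed, size_mode=size_mode, **problem_options)
        triplet, D = assembled_for_problem(pair)
        coords = None
        if any(mth in EUCLIDEAN_METHODS for mth in methods):
            _, coords = qee_transform(triplet, **qee_options)
        for mth in methods:
            if mth in EUCLIDEAN_METHODS:
                res = cluster_embedding(coords, k, EUCLIDEAN_METHODS[mth], seed=rep_seed)
            elif mth in ROWS_METHODS:
                res = distances_as_features_baseline(D, k, ROWS_METHODS[mth], seed=rep_seed)
            else:
                res = cluster_nonmetric(D, k, mth, seed=rep_seed)
            score, _ = score_result(pair, res.predicted_labels)
            scores[mth].append(score)

    result = BenchmarkResult(
        problem_tag=problem,
        scores={mth: np.array(v) for mth, v in scores.items()},
        n_replicates=n_replicates,
        size_mode=size_mode,
        seed=seed,
    )
    result.summarize()
    for i, a in enumerate(methods):
        for b in methods[i + 1 :]:
            p, r = compare_methods(result, a, b)
            result.comparisons[f"{a}|{b}"] = {"p_value": p, "effect_size_r": r}
    return result
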