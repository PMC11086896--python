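"""Clustering and classification, in the joint Euclidean space or on the
raw assembled distance matrix.

Euclidean-space methods (Ward, k-means, SOM, MLP, SVM) operate on qEE
coordinates; non-metric baselines (k-medoids, complete/average/single
linkage, spectral) operate directly on the assembled distance matrix.  The
theoretical origin point, when present, is always dropped before fitting:
it encodes magnitudes, not cluster membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform
from sklearn.cluster import KMeans, SpectralClustering
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .embedding import EmbeddingCoordinates

__all__ = [
    "ClusteringResult",
    "cluster_embedding",
    "cluster_nonmetric",
    "classify_ml",
    "distances_as_features_baseline",
]

NONMETRIC_METHODS = ("kmedoids", "complete", "average", "single", "spectral")


@dataclass
class ClusteringResult:
    predicted_labels: np.ndarray  # length m + n, origin excluded
    method_tag: str
    k: int
    params: dict = field(default_factory=dict)
    seed: int | None = None


def _drop_origin(coords: np.ndarray, item_ids: list[str]) -> np.ndarray:
    keep = [i for i, name in enumerate(item_ids) if not name.startswith("O:")]
    return coords[keep]


def cluster_embedding(
    coords: EmbeddingCoordinates,
    k: int,
    method: str = "ward",
    seed: int | None = None,
) -> ClusteringResult:
    """Ward (default, deterministic) or k-means on embedding coordinates.

    Ward is the advised pairing with the qEE: k-means degrades in the
    high-dimensional, nearly full-rank embedding space.
    """
    X = _drop_origin(coords.coords, coords.item_ids)
    return _cluster_points(X, k, method, seed)


def _cluster_points(
    X: np.ndarray, k: int, method: str, seed: int | None
) -> ClusteringResult:
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > X.shape[0]:
        raise ValueError("k exceeds the number of items")
    if method == "ward":
        Z = linkage(X, method="ward")
        labels = fcluster(Z, t=k, criterion="maxclust") - 1
    elif method == "kmeans":
        km = KMeans(n_clusters=k, n_init=10, random_state=_sk_seed(seed))
        labels = km.fit_predict(X)
    else:
        raise ValueError(f"unknown Euclidean method {method!r}")
    return ClusteringResult(np.asarray(labels), method, k, seed=seed)


def _sk_seed(seed: int | None) -> int | None:
    return None if seed is None else int(seed) % (2**31 - 1)


def _kmedoids(D: np.ndarray, k: int, seed: int | None, max_iter: int = 100) -> np.ndarray:
    """Seeded k-medoids: k-medoids++ initialization then alternating
    (Voronoi) assignment / medoid updates until stable."""
    n = D.shape[0]
    rng = np.random.default_rng(seed)
    medoids = [int(rng.integers(n))]
    while len(medoids) < k:
        dmin = D[:, medoids].min(axis=1)
        w = dmin**2
        total = w.sum()
        if total <= 0:
            # degenerate: duplicate points; pick any non-medoid
            candidates = [i for i in range(n) if i not in medoids]
            medoids.append(int(rng.choice(candidates)))
            continue
        medoids.append(int(rng.choice(n, p=w / total)))
    medoids = np.array(sorted(medoids))
    for _ in range(max_iter):
        labels = np.argmin(D[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if members.size == 0:
                continue
            sub = D[np.ix_(members, members)]
            new_medoids[c] = members[np.argmin(sub.sum(axis=1))]
        new_medoids = np.sort(new_medoids)
        if np.array_equal(new_medoids, medoids):
            break
        medoids = new_medoids
    return np.argmin(D[:, medoids], axis=1)


def cluster_nonmetric(
    D: np.ndarray,
    k: int,
    method: str = "kmedoids",
    seed: int | None = None,
) -> ClusteringResult:
    """Baselines applied directly to a (possibly non-Euclidean) distance
    matrix: k-medoids, the ultrametric linkages, or spectral clustering
    (Gaussian affinity with sigma = median off-diagonal distance)."""
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if k < 2 or k > D.shape[0]:
        raise ValueError("invalid k")
    if method in ("complete", "average", "single"):
        Z = linkage(squareform(D, checks=False), method=method)
        labels = fcluster(Z, t=k, criterion="maxclust") - 1
    elif method == "kmedoids":
        labels = _kmedoids(D, k, seed)
    elif method == "spectral":
        off = D[~np.eye(D.shape[0], dtype=bool)]
        sigma = np.median(off)
        if sigma <= 0:
            sigma = 1.0
        affinity = np.exp(-(D**2) / (2 * sigma**2))
        sc = SpectralClustering(
            n_clusters=k, affinity="precomputed", random_state=_sk_seed(seed)
        )
        labels = sc.fit_predict(affinity)
    else:
        raise ValueError(f"unknown non-metric method {method!r}")
    return ClusteringResult(np.asarray(labels), method, k, seed=seed)


def _som(
    X: np.ndarray,
    k: int,
    lr: float,
    max_iter: int,
    init: str,
    seed: int | None,
    init_labels: np.ndarray | None = None,
) -> np.ndarray:
    """Flat SOM: k code vectors; each step moves the best-matching unit of
    one sample toward it by the learning rate."""
    rng = np.random.default_rng(seed)
    if init == "random":
        nodes = rng.normal(
            loc=X.mean(axis=0), scale=X.std(axis=0) + 1e-12, size=(k, X.shape[1])
        )
    elif init == "ward":
        if init_labels is None:
            init_labels = _cluster_points(X, k, "ward", seed).predicted_labels
        nodes = np.vstack(
            [
                X[init_labels == c].mean(axis=0)
                if np.any(init_labels == c)
                else X.mean(axis=0)
                for c in range(k)
            ]
        )
    else:
        raise ValueError(f"unknown SOM init {init!r}")
    n = X.shape[0]
    for it in range(max_iter):
        x = X[int(rng.integers(n))]
        bmu = int(np.argmin(((nodes - x) ** 2).sum(axis=1)))
        nodes[bmu] += lr * (x - nodes[bmu])
    return np.argmin(cdist(X, nodes), axis=1)


def classify_ml(
    coords: EmbeddingCoordinates,
    k: int,
    method: str = "som",
    train_fraction: float | None = None,
    true_labels_for_training: np.ndarray | None = None,
    max_iter_factor: int = 3,
    lr: float = 0.5,
    init: str = "random",
    seed: int | None = None,
) -> ClusteringResult:
    """Machine-learning classification on the embedding coordinates.

    ``som`` is unsupervised (flat k code vectors, Euclidean BMU updates).
    ``mlp``/``svm`` are supervised: a stratified ``train_fraction`` split
    is fit with the known labels, the held-out items are predicted, and
    training items keep their training labels in the returned partition.
    The iteration cap is ``max_iter_factor`` times the number of items
    (default factor 3).
    """
    X = _drop_origin(coords.coords, coords.item_ids)
    n = X.shape[0]
    max_iter = max_iter_factor * n
    if method == "som":
        labels = _som(X, k, lr, max_iter, init, seed)
    elif method in ("mlp", "svm"):
        if train_fraction is None or not (0 < train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        if true_labels_for_training is None:
            raise ValueError("supervised methods need training labels")
        y = np.asarray(true_labels_for_training)
        idx_train, idx_test = train_test_split(
            np.arange(n),
            train_size=train_fraction,
            stratify=y,
            random_state=_sk_seed(seed),
        )
        if method == "mlp":
            clf = MLPClassifier(
                hidden_layer_sizes=(100,),
                max_iter=max_iter,
                random_state=_sk_seed(seed),
            )
        else:
            clf = SVC(kernel="rbf", max_iter=max_iter, random_state=_sk_seed(seed))
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")  # convergence warnings at the capped iters
            clf.fit(X[idx_train], y[idx_train])
            pred = clf.predict(X[idx_test])
        labels = np.empty(n, dtype=int)
        labels[idx_train] = y[idx_train]
        labels[idx_test] = pred
    else:
        raise ValueError(f"unknown ML method {method!r}")
    return ClusteringResult(
        np.asarray(labels),
        method,
        k,
        params={"max_iter": max_iter, "lr": lr, "init": init,
                "train_fraction": train_fraction},
        seed=seed,
    )


def distances_as_features_baseline(
    D: np.ndarray,
    k: int,
    method: str = "ward",
    seed: int | None = None,
) -> ClusteringResult:
    """Negative control: treat each row of the assembled distance matrix as
    a coordinate vector and run a Euclidean method on those rows."""
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("expected a symmetric square distance matrix")
    import warnings

    with warnings.catch_warnings():
        # scipy warns that the rows look like a distance matrix; using the
        # rows as coordinates is exactly the point of this control
        warnings.simplefilter("ignore")
        res = _cluster_points(D, k, method, seed)
    res.method_tag = f"rows_{method}"
    return res
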