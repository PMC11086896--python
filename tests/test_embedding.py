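"""qEE core: Schoenberg criterion, shift constants, joint distance, MDS."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist, pdist, squareform
from scipy.stats import spearmanr

import jointclust as jc
from jointclust.distances import DistanceTriplet, assemble
from jointclust.embedding import (
    EmbeddingConstants,
    _double_centered_gram,
    build_joint_distance,
    embed_coordinates,
    euclideanize_similarity,
    find_constants,
    schoenberg_is_euclidean,
)
from conftest import random_triplet


def star_metric() -> np.ndarray:
    """Center at distance 1 from three leaves, leaves pairwise 2: a metric
    with no Euclidean realization (the leaves would need to be collinear
    through the center in three directions at once)."""
    D = np.full((4, 4), 2.0)
    D[0, :] = D[:, 0] = 1.0
    np.fill_diagonal(D, 0.0)
    return D


# ---------------------------------------------------------------------------
# Schoenberg criterion
# ---------------------------------------------------------------------------

def test_collinear_points_are_euclidean():
    pts = np.array([[0.0], [1.0], [2.0]])
    assert schoenberg_is_euclidean(cdist(pts, pts))


def test_star_metric_is_not_euclidean():
    D = star_metric()
    assert not schoenberg_is_euclidean(D)
    # independent oracle: smallest eigenvalue of the double-centered matrix
    w = np.linalg.eigvalsh(_double_centered_gram(D))
    assert w[0] < -1e-6


def test_shifted_star_metric_becomes_euclidean():
    D = star_metric()
    shift = 10.0
    L = np.sqrt(D**2 + shift)
    np.fill_diagonal(L, 0.0)
    assert schoenberg_is_euclidean(L)


def test_schoenberg_rejects_invalid_input():
    with pytest.raises(ValueError):
        schoenberg_is_euclidean(np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValueError):
        schoenberg_is_euclidean(-np.ones((2, 2)))


# ---------------------------------------------------------------------------
# zeta
# ---------------------------------------------------------------------------

def test_zeta_by_brute_force_enumeration():
    trip = DistanceTriplet(
        np.array([[0.0, 1.0], [1.0, 0.0]]),
        np.array([[0.0, 1.0], [1.0, 0.0]]),
        np.ones((2, 2)),
    )
    # anchored terms g(x, y) = |dX(x, x1)^2 + dXY(x1, y)^2 - dXY(x, y)^2| / 2
    g = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            g[i, j] = abs(trip.dX[i, 0] ** 2 + trip.dXY[0, j] ** 2 - trip.dXY[i, j] ** 2) / 2
    expected = max(g.sum(axis=1).max(), g.sum(axis=0).max())
    zeta, anchor = jc.compute_zeta(trip)
    assert anchor == "x1"
    assert zeta == pytest.approx(expected)
    assert jc.compute_zeta(trip, mode="max")[0] == pytest.approx(g.max())
    assert jc.compute_zeta(trip, mode="sum")[0] == pytest.approx(g.sum())


def test_zeta_vanishes_for_pythagorean_triplet():
    # d_cross(a, b)^2 = d_sim(a, x1)^2 + d_cross(x1, b)^2 for all pairs:
    # X on one axis, Y offset orthogonally from the anchor x1
    x = np.array([[0.0, 0.0], [1.0, 0.0]])
    y = np.array([[0.0, 1.0], [0.0, 2.0]])
    dXY = np.sqrt((x[:, 0][:, None]) ** 2 + (y[:, 1][None, :]) ** 2)
    trip = DistanceTriplet(cdist(x, x), cdist(y, y), dXY)
    zeta, _ = jc.compute_zeta(trip)
    assert zeta == pytest.approx(0.0, abs=1e-12)


def test_zeta_nonnegative_and_anchor_selection():
    for seed in range(5):
        trip = random_triplet(seed)
        assert jc.compute_zeta(trip)[0] >= 0
    trip = random_triplet(1)
    trip.dX_is_euclidean = False
    assert jc.compute_zeta(trip)[1] == "y1"
    trip.dY_is_euclidean = False
    with pytest.raises(ValueError, match="euclideanize"):
        jc.compute_zeta(trip)


# ---------------------------------------------------------------------------
# constant search
# ---------------------------------------------------------------------------

def test_find_constants_satisfies_schoenberg_postcondition():
    for seed in range(5):
        trip = random_triplet(seed)
        c = find_constants(trip)
        L = build_joint_distance(trip, c).lambda_matrix
        assert schoenberg_is_euclidean(L)
        assert 2 + c.c1 + c.c2 - c.c3 == pytest.approx(0.0)


def test_find_constants_random_init_reproducible():
    trip = random_triplet(3)
    a = find_constants(trip, init="random", seed=5)
    b = find_constants(trip, init="random", seed=5)
    assert (a.c1, a.c2, a.c3) == (b.c1, b.c2, b.c3)


def test_already_euclidean_triplet_converges_first_iteration():
    # points in the plane: the assembled matrix is itself Euclidean, and
    # shifting squared distances by a constant keeps it embeddable
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(7, 2))
    D = cdist(pts, pts)
    trip = DistanceTriplet(D[:4, :4], D[4:, 4:], D[:4, 4:])
    c = find_constants(trip)
    assert c.iterations_used == 1
    assert c.zeta > 0


def test_iteration_cap_raises():
    trip = random_triplet(0)
    with pytest.raises(RuntimeError, match="failed"):
        find_constants(trip, max_iterations=0)


# ---------------------------------------------------------------------------
# joint distance and coordinates
# ---------------------------------------------------------------------------

def test_joint_distance_shift_identity():
    trip = random_triplet(4)
    c = find_constants(trip)
    joint = build_joint_distance(trip, c)
    D = assemble(trip)
    L = joint.lambda_matrix
    off = ~np.eye(L.shape[0], dtype=bool)
    assert np.all(np.diag(L) == 0)
    assert np.allclose((L**2 - D**2)[off], c.shift)


def test_origin_distance_encodes_magnitude():
    trip = random_triplet(5, m=3, n=3)
    zeta, _ = jc.compute_zeta(trip)
    c3 = 7.0 / zeta  # choose c3 so that the shift c3*zeta = 7
    c = EmbeddingConstants(c1=c3 - 2.5, c2=0.5, c3=c3, zeta=zeta, anchor="x1",
                           iterations_used=1)
    mags = np.full(6, 3.0)
    joint = build_joint_distance(trip, c, include_origin=True, magnitudes=mags)
    assert joint.lambda_matrix[0, -1] == pytest.approx(4.0)  # sqrt(9 + 7)
    with pytest.raises(ValueError, match="magnitudes"):
        build_joint_distance(trip, c, include_origin=True)


def test_mds_round_trip_reproduces_joint_distance():
    trip = random_triplet(6, m=8, n=7)
    joint, coords = jc.qee_transform(trip)
    L_hat = squareform(pdist(coords.coords))
    L = joint.lambda_matrix
    off = L[~np.eye(L.shape[0], dtype=bool)]
    rel_err = np.max(np.abs(L_hat - L)) / off.max()
    assert rel_err <= 1e-6
    assert coords.coords.shape[1] <= L.shape[0] - 1


def test_equal_distances_embed_as_equilateral_triangle():
    s = 2.5
    L = np.full((3, 3), s)
    np.fill_diagonal(L, 0.0)
    c = EmbeddingConstants(0.5, 2.0, 4.5, 0.0, "x1", 1)
    joint = jc.JointDistance(L, c, False, ["X:0", "X:1", "Y:0"])
    coords = embed_coordinates(joint)
    d = pdist(coords.coords)
    assert np.allclose(d, s)


def test_embed_rejects_non_euclidean_matrix():
    c = EmbeddingConstants(0.5, 2.0, 4.5, 0.0, "x1", 1)
    joint = jc.JointDistance(star_metric(), c, False, list("abcd"))
    with pytest.raises(ValueError, match="not Euclidean"):
        embed_coordinates(joint)


# ---------------------------------------------------------------------------
# order preservation & metric property
# ---------------------------------------------------------------------------

def test_order_preservation_is_exact():
    for seed in range(4):
        trip = random_triplet(seed, m=7, n=6)
        joint, _ = jc.qee_transform(trip)
        D = assemble(trip)
        off = ~np.eye(D.shape[0], dtype=bool)
        rho = spearmanr(D[off] ** 2, joint.lambda_matrix[off] ** 2).statistic
        assert rho == 1.0


def test_joint_distance_satisfies_triangle_inequality():
    trip = random_triplet(9, m=6, n=6)
    joint, _ = jc.qee_transform(trip)
    L = joint.lambda_matrix
    n = L.shape[0]
    rng = np.random.default_rng(0)
    for _ in range(200):
        i, j, k = rng.integers(0, n, size=3)
        assert L[i, j] <= L[i, k] + L[k, j] + 1e-9


# ---------------------------------------------------------------------------
# duplicate-set euclideanization
# ---------------------------------------------------------------------------

def test_euclideanize_output_is_euclidean_and_order_equivalent():
    D = star_metric()
    out = euclideanize_similarity(D)
    assert schoenberg_is_euclidean(out)
    off = ~np.eye(4, dtype=bool)
    # squared output = squared input + one constant
    diff = out[off] ** 2 - D[off] ** 2
    assert np.allclose(diff, diff[0])
    # ties (the star metric has repeated distances) pick up fp jitter from
    # the sqrt/square round trip, so allow rounding-level slack here
    assert spearmanr(out[off] ** 2, D[off] ** 2).statistic >= 1 - 1e-9


def test_euclideanize_idempotent_on_euclidean_input():
    pts = np.random.default_rng(1).normal(size=(5, 2))
    D = cdist(pts, pts)
    out = euclideanize_similarity(D)
    assert schoenberg_is_euclidean(out)
    off = ~np.eye(5, dtype=bool)
    diff = out[off] ** 2 - D[off] ** 2
    assert np.allclose(diff, diff[0])


def test_euclideanize_rejects_non_euclidean_placeholder():
    with pytest.raises(ValueError, match="placeholder"):
        euclideanize_similarity(star_metric(), placeholder=star_metric())


def test_nonmetric_triplet_routes_through_euclideanization():
    # both similarity blocks flagged non-Euclidean (e.g. L3-norm distances)
    trip = random_triplet(10)
    trip3 = DistanceTriplet(
        trip.dX, trip.dY, trip.dXY, dX_is_euclidean=False, dY_is_euclidean=False
    )
    joint, coords = jc.qee_transform(trip3)
    assert schoenberg_is_euclidean(joint.lambda_matrix)
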