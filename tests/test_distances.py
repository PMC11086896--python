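"""Distance matrices: Lp similarity, KS/Spearman/Granger association, assembly."""

import numpy as np
import pytest
from scipy import stats

import jointclust as jc
from jointclust.features import FeatureMatrix
from jointclust.distances import (
    DistanceTriplet,
    assemble,
    extract_blocks,
    granger_association,
    granger_pvalue,
    ks_association,
    pairwise_norm_distance,
    spearman_association,
)

EPS = 1e-9


# ---------------------------------------------------------------------------
# Lp similarity
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "points,p,expected",
    [([[0, 0], [3, 4]], 2.0, 5.0), ([[0], [2]], 3.0, 2.0)],
)
def test_norm_distance_known_values(points, p, expected):
    d = pairwise_norm_distance(FeatureMatrix(np.array(points, float), "identity"), p)
    assert d[0, 1] == pytest.approx(expected)


def test_norm_distance_is_pseudo_metric():
    rng = np.random.default_rng(0)
    f = FeatureMatrix(rng.normal(size=(12, 4)), "identity")
    for p in (1.0, 2.0, 3.0):
        d = pairwise_norm_distance(f, p)
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        assert np.all(d >= 0)
        # triangle inequality on all triples
        for i in range(12):
            for j in range(12):
                for k in range(12):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


def test_norm_distance_rejects_nonfinite():
    f = FeatureMatrix(np.zeros((2, 2)), "identity")
    f.values[0, 0] = np.nan
    with pytest.raises(ValueError):
        pairwise_norm_distance(f)


# ---------------------------------------------------------------------------
# KS association
# ---------------------------------------------------------------------------

def test_ks_identical_samples_distance_is_eps():
    s = np.random.default_rng(1).normal(size=100)
    d = ks_association([s], [s.copy()], eps=EPS)
    assert d[0, 0] == pytest.approx(EPS)


def test_ks_disjoint_samples_distance_near_one():
    rng = np.random.default_rng(2)
    x, y = rng.normal(size=300), rng.normal(size=300) + 10
    d = ks_association([x], [y], eps=EPS)
    assert d[0, 0] == pytest.approx(1.0 + EPS, abs=1e-12)


def test_ks_matches_scipy_asymptotic():
    rng = np.random.default_rng(3)
    xs = [rng.normal(size=n) for n in (120, 300, 251)]
    ys = [rng.normal(loc=mu, size=n) for mu, n in ((0, 200), (0.3, 300), (1.0, 77))]
    d = ks_association(xs, ys, eps=EPS)
    for i, x in enumerate(xs):
        for j, y in enumerate(ys):
            ref = stats.ks_2samp(x, y, method="asymp").pvalue
            assert d[i, j] == pytest.approx(EPS + 1 - ref, abs=1e-12)


def test_ks_invariant_to_permuting_observations():
    rng = np.random.default_rng(4)
    x, y = rng.normal(size=80), rng.normal(size=90)
    d1 = ks_association([x], [y])
    d2 = ks_association([rng.permutation(x)], [rng.permutation(y)])
    assert d1[0, 0] == pytest.approx(d2[0, 0])


def test_ks_bounds_and_symmetry_of_roles():
    rng = np.random.default_rng(5)
    xs = [rng.normal(size=60) for _ in range(3)]
    ys = [rng.uniform(size=60) for _ in range(4)]
    d = ks_association(xs, ys, eps=EPS)
    assert np.all((d >= EPS) & (d <= 1 + EPS))
    assert np.allclose(d, ks_association(ys, xs, eps=EPS).T)


# ---------------------------------------------------------------------------
# Spearman association
# ---------------------------------------------------------------------------

def test_spearman_monotone_relations_give_eps():
    x = np.random.default_rng(6).normal(size=200)
    d = spearman_association([x, x], [x**3, -x], eps=EPS)
    assert d[0, 0] == pytest.approx(EPS, abs=1e-12)  # y = x^3
    assert d[1, 1] == pytest.approx(EPS, abs=1e-12)  # y = -x


def test_spearman_matches_scipy():
    rng = np.random.default_rng(7)
    xs = [rng.normal(size=50) for _ in range(3)]
    ys = [rng.normal(size=50) for _ in range(3)]
    d = spearman_association(xs, ys, eps=EPS)
    for i in range(3):
        for j in range(3):
            rho = stats.spearmanr(xs[i], ys[j]).statistic
            assert d[i, j] == pytest.approx(EPS + 1 - abs(rho), abs=1e-10)


def test_spearman_independent_samples_near_max():
    # null Monte-Carlo: |rho| < 0.15 in at least 95% of repetitions
    rng = np.random.default_rng(8)
    hits = 0
    n_rep = 60
    for _ in range(n_rep):
        d = spearman_association([rng.normal(size=300)], [rng.normal(size=300)])
        hits += d[0, 0] > 1e-9 + 1 - 0.15
    assert hits / n_rep >= 0.95


def test_spearman_constant_sample_maximal_with_warning():
    x = np.ones(20)
    y = np.random.default_rng(9).normal(size=20)
    with pytest.warns(UserWarning, match="constant"):
        d = spearman_association([x], [y], eps=EPS)
    assert d[0, 0] == pytest.approx(1 + EPS)


# ---------------------------------------------------------------------------
# Granger association
# ---------------------------------------------------------------------------

def _ar_coupled_timecourse(seed, T=60, noise=0.05):
    """3-row time-courses where each y row follows x lagged by one step."""
    rng = np.random.default_rng(seed)
    x = np.cumsum(rng.normal(size=(3, T + 1)), axis=1)  # random walks
    y = x[:, :-1] + noise * rng.normal(size=(3, T))
    return x[:, 1:], y


def test_granger_pvalue_matches_statsmodels():
    sm_tsa = pytest.importorskip("statsmodels.tsa.stattools")
    rng = np.random.default_rng(10)
    for lag in (1, 2):
        x = rng.normal(size=40)
        y = np.roll(x, 1) + 0.1 * rng.normal(size=40)
        res = sm_tsa.grangercausalitytests(
            np.column_stack([y, x]), maxlag=[lag], verbose=False
        )
        ref = res[lag][0]["ssr_ftest"][1]
        assert granger_pvalue(x, y, lag) == pytest.approx(ref, rel=1e-6)


def test_granger_detects_constructed_causality():
    x, y = _ar_coupled_timecourse(11)
    d = granger_association([x], [y], eps=EPS, lag=1)
    assert d[0, 0] < EPS + 0.05


def test_granger_null_is_large_on_average():
    rng = np.random.default_rng(12)
    entries = []
    for _ in range(30):
        x = rng.normal(size=(3, 40))
        y = rng.normal(size=(3, 40))
        entries.append(granger_association([x], [y], eps=EPS)[0, 0])
    # per moment min of two independent uniform p-values has mean 1/3
    assert np.mean(entries) > 0.2


def test_granger_bounds_and_short_series_error():
    rng = np.random.default_rng(13)
    d = granger_association(
        [rng.normal(size=(3, 30))], [rng.normal(size=(3, 30))], eps=EPS
    )
    assert np.all((d > EPS) & (d <= 1 + EPS))
    with pytest.raises(ValueError, match="short"):
        granger_pvalue(np.zeros(5), np.zeros(5), lag=2)


def test_granger_literal_direction_mode():
    x, y = _ar_coupled_timecourse(14)
    d_xy = granger_association([x], [y], eps=EPS, direction="x_to_y_only")
    d_yx = granger_association([y], [x], eps=EPS, direction="x_to_y_only")
    # x causes y: testing x->y yields small p, y->x does not
    assert d_xy[0, 0] < d_yx[0, 0]


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def test_assemble_block_layout():
    dX = np.array([[0.0, 1.0], [1.0, 0.0]])
    dY = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0.0]])
    dXY = np.arange(1.0, 7.0).reshape(2, 3)
    D = assemble(DistanceTriplet(dX, dY, dXY))
    assert D.shape == (5, 5)
    assert np.allclose(D, D.T)
    assert np.array_equal(D[:2, :2], dX)
    assert np.array_equal(D[2:, 2:], dY)
    assert np.array_equal(D[:2, 2:], dXY)


def test_assemble_association_scaling_only_affects_cross_block():
    trip = DistanceTriplet(
        np.array([[0.0, 1.0], [1.0, 0.0]]),
        np.array([[0.0, 2.0], [2.0, 0.0]]),
        np.ones((2, 2)),
        scale_factors=(1.0, 1.0, 0.5),
    )
    D = assemble(trip)
    assert np.allclose(D[:2, 2:], 0.5)
    assert D[0, 1] == 1.0 and D[2, 3] == 2.0


def test_all_zero_association_rejected():
    with pytest.raises(ValueError, match="identically zero"):
        DistanceTriplet(
            np.array([[0.0, 1.0], [1.0, 0.0]]),
            np.array([[0.0, 1.0], [1.0, 0.0]]),
            np.zeros((2, 2)),
        )


def test_assemble_round_trips_through_extract_blocks():
    rng = np.random.default_rng(15)
    from scipy.spatial.distance import cdist

    p = rng.normal(size=(4, 2))
    q = rng.normal(size=(3, 2))
    trip = DistanceTriplet(cdist(p, p), cdist(q, q), rng.uniform(0.1, 1, (4, 3)))
    dX, dY, dXY = extract_blocks(assemble(trip), 4)
    assert np.array_equal(dX, trip.dX)
    assert np.array_equal(dY, trip.dY)
    assert np.array_equal(dXY, trip.dXY)


def test_dimension_mismatch_rejected():
    with pytest.raises(ValueError, match="m x n"):
        DistanceTriplet(
            np.zeros((2, 2)), np.zeros((3, 3)), np.ones((3, 2))
        )
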