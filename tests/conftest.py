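import numpy as np
import pytest

import jointclust as jc


@pytest.fixture(scope="session")
def small_distribution_pair():
    """A reduced distribution-family dataset (fast, still 4 families)."""
    return jc.generate_distribution_data(n_per_family=10, n_obs=120, seed=101)


@pytest.fixture(scope="session")
def small_triplet(small_distribution_pair):
    triplet, _ = jc.assembled_for_problem(small_distribution_pair)
    return triplet


@pytest.fixture(scope="session")
def small_embedding(small_triplet):
    joint, coords = jc.qee_transform(small_triplet)
    return joint, coords


@pytest.fixture(scope="session")
def full_distribution_run():
    """One full-size distribution benchmark instance with its embedding."""
    pair = jc.generate_distribution_data(seed=42)
    triplet, D = jc.assembled_for_problem(pair)
    joint, coords = jc.qee_transform(triplet)
    return pair, triplet, D, joint, coords


def random_triplet(seed: int, m: int = 6, n: int = 5) -> jc.DistanceTriplet:
    """A valid random distance triplet with Euclidean similarity blocks."""
    rng = np.random.default_rng(seed)
    px = rng.normal(size=(m, 3))
    py = rng.normal(size=(n, 3))
    from scipy.spatial.distance import cdist

    return jc.DistanceTriplet(
        dX=cdist(px, px),
        dY=cdist(py, py),
        dXY=rng.uniform(0.1, 2.0, size=(m, n)),
    )
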