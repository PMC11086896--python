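"""Synthetic benchmark datasets with known cluster and pairing structure.

Three dataset families are generated, each split into two disjoint datasets
X and Y whose items must be co-clustered:

* ``distributions`` — sample vectors drawn from four families of
  distributions (normal, uniform, Pareto, Poisson), five parameterizations
  per family; the true clusters are the families.
* ``correlated`` — paired sample vectors from ten bivariate normal
  distributions; the first coordinate of each draw goes to X, the second
  to Y; the true clusters are the generating distributions.
* ``two_gene`` — moment time-courses (mean, variance, skewness of mRNA
  counts over many exact stochastic simulations) of two-gene regulatory
  models with no, mono-directional, or bi-directional repression; gene A
  goes to X, gene B to Y, and interacting genes share a true cluster.

All generators are deterministic given (seed, parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from numba import njit

__all__ = [
    "LabeledDatasetPair",
    "TwoGeneModelSpec",
    "generate_distribution_data",
    "generate_correlated_data",
    "simulate_two_gene_model",
    "generate_two_gene_data",
    "DISTRIBUTION_FAMILIES",
    "default_bivariate_params",
]

SizeMode = Literal["fixed", "random"]


@dataclass
class LabeledDatasetPair:
    """Two disjoint datasets with ground-truth labels and pairing ids.

    ``X_items``/``Y_items`` hold either 1-d observation vectors or
     3 x T moment time-course matrices.  ``pairing_ids`` link each X item
    to the Y item generated by the same unit (same draw / same model
    instance); they are aligned with the item lists.
    """

    X_items: list[np.ndarray]
    Y_items: list[np.ndarray]
    true_labels_X: np.ndarray
    true_labels_Y: np.ndarray
    pairing_ids_X: np.ndarray
    pairing_ids_Y: np.ndarray
    problem_tag: str
    seed: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.X_items) < 2 or len(self.Y_items) < 2:
            raise ValueError("each dataset needs at least two items")
        if len(self.true_labels_X) != len(self.X_items):
            raise ValueError("label / item length mismatch in X")
        if len(self.true_labels_Y) != len(self.Y_items):
            raise ValueError("label / item length mismatch in Y")
        px, py = set(self.pairing_ids_X.tolist()), set(self.pairing_ids_Y.tolist())
        if px != py:
            raise ValueError("pairing ids must match between X and Y")

    @property
    def m(self) -> int:
        return len(self.X_items)

    @property
    def n(self) -> int:
        return len(self.Y_items)

    @property
    def n_true_clusters(self) -> int:
        return len(set(self.true_labels_X.tolist()) | set(self.true_labels_Y.tolist()))


def _check_size_mode(size_mode: str) -> None:
    if size_mode not in ("fixed", "random"):
        raise ValueError(f"size_mode must be 'fixed' or 'random', got {size_mode!r}")


# ---------------------------------------------------------------------------
# Problem 1: families of distributions
# ---------------------------------------------------------------------------

# Five parameterizations per family.  Each entry is (name, sampler) where the
# sampler maps (rng, param, size) -> observations.
DISTRIBUTION_FAMILIES: dict[str, tuple] = {
    "normal": ([0.0, 1.0, 2.0, 3.0, 4.0], lambda rng, mu, size: rng.normal(mu, 1.0, size)),
    "uniform": ([1.0, 2.0, 3.0, 4.0, 5.0], lambda rng, b, size: rng.uniform(0.0, b, size)),
    "pareto": ([1.0, 1.5, 2.0, 2.5, 3.0], lambda rng, a, size: rng.pareto(a, size) + 1.0),
    "poisson": ([1.0, 3.0, 5.0, 7.0, 9.0], lambda rng, lam, size: rng.poisson(lam, size).astype(float)),
}


def generate_distribution_data(
    n_per_family: int = 25,
    n_obs: int = 300,
    seed: int = 0,
    size_mode: SizeMode = "fixed",
) -> LabeledDatasetPair:
    """Sample vectors from four distribution families, for X and Y.

    ``n_per_family`` sample vectors per family go into each of X and Y
    (independent draws), spread evenly over the family's five
    parameterizations.  True labels are the family index (4 clusters);
    the i-th X vector of a family is paired with the i-th Y vector.
    With ``size_mode='random'`` the per-family count is drawn uniformly
    from 2..n_per_family.
    """
    _check_size_mode(size_mode)
    if n_per_family < 1:
        raise ValueError("n_per_family must be >= 1")
    if n_obs < 2:
        raise ValueError("n_obs must be >= 2")
    rng = np.random.default_rng(seed)

    X_items, Y_items, lab_X, lab_Y, pid_X, pid_Y = [], [], [], [], [], []
    pid = 0
    for fam_idx, (fam, (params, sampler)) in enumerate(DISTRIBUTION_FAMILIES.items()):
        count = n_per_family
        if size_mode == "random":
            count = int(rng.integers(2, n_per_family + 1))
        for i in range(count):
            param = params[i % len(params)]
            X_items.append(np.asarray(sampler(rng, param, n_obs), dtype=float))
            Y_items.append(np.asarray(sampler(rng, param, n_obs), dtype=float))
            lab_X.append(fam_idx)
            lab_Y.append(fam_idx)
            pid_X.append(pid)
            pid_Y.append(pid)
            pid += 1
    return LabeledDatasetPair(
        X_items,
        Y_items,
        np.array(lab_X),
        np.array(lab_Y),
        np.array(pid_X),
        np.array(pid_Y),
        problem_tag="distributions",
        seed=seed,
        meta={"families": list(DISTRIBUTION_FAMILIES), "n_obs": n_obs},
    )


# ---------------------------------------------------------------------------
# Problem 2: correlated bivariate normal variables
# ---------------------------------------------------------------------------

def default_bivariate_params(n_dists: int = 10) -> list[dict]:
    """Means on a grid, unit variances, correlations alternating in sign
    with |rho| spanning 0.4 .. 0.95."""
    params = []
    for k in range(n_dists):
        rho = 0.4 + 0.55 * k / max(n_dists - 1, 1)
        if k % 2 == 1:
            rho = -rho
        params.append({"mean": (2.0 * k, 2.0 * k), "sd": (1.0, 1.0), "rho": rho})
    return params


def generate_correlated_data(
    n_pairs_per_dist: int = 25,
    n_obs: int = 300,
    seed: int = 0,
    size_mode: SizeMode = "fixed",
    params: Sequence[dict] | None = None,
) -> LabeledDatasetPair:
    """Paired samples from bivariate normal distributions.

    Each draw produces one X item (first coordinate) and one Y item
    (second coordinate) sharing a pairing id; true labels are the
    distribution index.
    """
    _check_size_mode(size_mode)
    if n_pairs_per_dist < 1:
        raise ValueError("n_pairs_per_dist must be >= 1")
    if n_obs < 3:
        raise ValueError("n_obs must be >= 3 for correlation to be defined")
    if params is None:
        params = default_bivariate_params()
    rng = np.random.default_rng(seed)

    X_items, Y_items, lab_X, lab_Y, pids = [], [], [], [], []
    pid = 0
    for k, p in enumerate(params):
        sx, sy = p["sd"]
        cov = np.array(
            [[sx**2, p["rho"] * sx * sy], [p["rho"] * sx * sy, sy**2]]
        )
        count = n_pairs_per_dist
        if size_mode == "random":
            count = int(rng.integers(2, n_pairs_per_dist + 1))
        for _ in range(count):
            draw = rng.multivariate_normal(p["mean"], cov, size=n_obs)
            X_items.append(draw[:, 0].copy())
            Y_items.append(draw[:, 1].copy())
            lab_X.append(k)
            lab_Y.append(k)
            pids.append(pid)
            pid += 1
    pids = np.array(pids)
    return LabeledDatasetPair(
        X_items,
        Y_items,
        np.array(lab_X),
        np.array(lab_Y),
        pids,
        pids.copy(),
        problem_tag="correlated",
        seed=seed,
        meta={"params": list(params), "n_obs": n_obs},
    )


# ---------------------------------------------------------------------------
# Problem 3: two-gene stochastic regulatory models
# ---------------------------------------------------------------------------

ModelClass = Literal["No-I", "Mono-I", "Bi-I"]


@dataclass
class TwoGeneModelSpec:
    """Parameterization of a stochastic two-gene birth-death model.

    Gene g is born at rate ``k0_g * (1 + trend * t) * f(other count)``
    and degraded at ``gamma_g * count``, where the repression factor is
    ``f(r) = 1 / (1 + strength * (r / K)**hill)``.  A zero strength means
    no regulation (f = 1).  ``model_class`` constrains the strengths:
    No-I has both zero, Mono-I regulates A by B only, Bi-I both.
    """

    model_class: ModelClass
    birth_A: float = 4.0
    birth_B: float = 4.0
    gamma_A: float = 0.25
    gamma_B: float = 0.25
    strength_A_by_B: float = 0.0
    strength_B_by_A: float = 0.0
    K_A: float = 6.0
    K_B: float = 6.0
    hill: float = 2.0
    trend: float = 0.15
    n_trajectories: int = 4000
    time_grid: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 20.0, 51)
    )

    def __post_init__(self) -> None:
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        if np.any(np.diff(self.time_grid) <= 0):
            raise ValueError("time_grid must be strictly increasing")
        for r in (self.birth_A, self.birth_B, self.gamma_A, self.gamma_B):
            if r < 0:
                raise ValueError("rates must be nonnegative")
        if self.trend < 0:
            raise ValueError("trend must be nonnegative")
        if self.model_class == "No-I":
            if self.strength_A_by_B or self.strength_B_by_A:
                raise ValueError("No-I model must have zero regulation strengths")
        elif self.model_class == "Mono-I":
            if not (self.strength_A_by_B > 0 and self.strength_B_by_A == 0):
                raise ValueError("Mono-I regulates A by B only")
        elif self.model_class == "Bi-I":
            if not (self.strength_A_by_B > 0 and self.strength_B_by_A > 0):
                raise ValueError("Bi-I regulates in both directions")
        else:
            raise ValueError(f"unknown model_class {self.model_class!r}")


def default_two_gene_spec(
    model_class: ModelClass,
    n_trajectories: int = 4000,
    strength: float = 5.0,
    **overrides,
) -> TwoGeneModelSpec:
    """Spec for one of the three interaction classes with default rates."""
    s_ab = strength if model_class in ("Mono-I", "Bi-I") else 0.0
    s_ba = strength if model_class == "Bi-I" else 0.0
    return TwoGeneModelSpec(
        model_class=model_class,
        strength_A_by_B=s_ab,
        strength_B_by_A=s_ba,
        n_trajectories=n_trajectories,
        **overrides,
    )


@njit(cache=False)
def _ssa_kernel(
    seed,
    t_grid,
    n_traj,
    k0a,
    k0b,
    trend,
    ga,
    gb,
    s_ab,
    s_ba,
    Ka,
    Kb,
    hill,
):  # pragma: no cover - exercised through simulate_two_gene_model
    """Exact SSA (Ogata thinning for the time-dependent birth rates).

    Every event changes one gene count by exactly +-1.  States are
    recorded on t_grid by piecewise-constant interpolation (state just
    before the first event after each grid time).
    """
    np.random.seed(seed)
    G = t_grid.shape[0]
    T = t_grid[G - 1]
    out = np.zeros((n_traj, 2, G), dtype=np.int64)
    boost = 1.0 + trend * T
    for r in range(n_traj):
        t = 0.0
        na = 0
        nb = 0
        gi = 0
        while gi < G:
            fa = 1.0 / (1.0 + s_ab * (nb / Ka) ** hill)
            fb = 1.0 / (1.0 + s_ba * (na / Kb) ** hill)
            lam_bar = k0a * boost * fa + k0b * boost * fb + ga * na + gb * nb
            if lam_bar <= 0.0:
                tn = T + 1.0
            else:
                tn = t + np.random.exponential(1.0 / lam_bar)
            while gi < G and t_grid[gi] < tn:
                out[r, 0, gi] = na
                out[r, 1, gi] = nb
                gi += 1
            if gi >= G:
                break
            scale = 1.0 + trend * tn
            ba = k0a * scale * fa
            bb = k0b * scale * fb
            u = np.random.random() * lam_bar
            if u < ba:
                na += 1
            elif u < ba + bb:
                nb += 1
            elif u < ba + bb + ga * na:
                na -= 1
            elif u < ba + bb + ga * na + gb * nb:
                nb -= 1
            # else: thinning rejection, only time advances
            t = tn
    return out


def _moments(counts: np.ndarray) -> np.ndarray:
    """Stack (mean, variance, skewness) over trajectories: (T,) arrays -> 3 x G."""
    mean = counts.mean(axis=0)
    # sample variance (ddof=1); skewness uses population moments (g1)
    var = counts.var(axis=0, ddof=1)
    centered = counts - mean
    m2 = np.mean(centered**2, axis=0)
    m3 = np.mean(centered**3, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(m2 > 0, m3 / np.where(m2 > 0, m2, 1.0) ** 1.5, 0.0)
    return np.vstack([mean, var, skew])


def simulate_two_gene_model(
    spec: TwoGeneModelSpec, seed: int, return_trajectories: bool = False
):
    """Run the exact stochastic simulation and return moment time-courses.

    Returns ``(moments_A, moments_B)``, each a 3 x |time_grid| array of
    (mean, variance, skewness), optionally followed by the raw
    grid-sampled count trajectories (n_traj x 2 x |time_grid|).
    """
    if spec.n_trajectories < 2:
        raise ValueError("need at least 2 trajectories for the variance")
    counts = _ssa_kernel(
        int(seed) % (2**31 - 1),
        spec.time_grid,
        spec.n_trajectories,
        spec.birth_A,
        spec.birth_B,
        spec.trend,
        spec.gamma_A,
        spec.gamma_B,
        spec.strength_A_by_B,
        spec.strength_B_by_A,
        spec.K_A,
        spec.K_B,
        spec.hill,
    )
    mom_a = _moments(counts[:, 0, :].astype(float))
    mom_b = _moments(counts[:, 1, :].astype(float))
    if return_trajectories:
        return mom_a, mom_b, counts
    return mom_a, mom_b


_MODEL_CLASSES = ("No-I", "Mono-I", "Bi-I")
# Label rule: interacting genes of one instance share a cluster; the two
# non-interacting genes of a No-I instance get separate clusters -> 4 classes.
_LABELS_X = {"No-I": 0, "Mono-I": 2, "Bi-I": 3}
_LABELS_Y = {"No-I": 1, "Mono-I": 2, "Bi-I": 3}


def generate_two_gene_data(
    n_per_model: int = 25,
    n_trajectories: int = 4000,
    seed: int = 0,
    size_mode: SizeMode = "fixed",
    rate_jitter: float = 0.0,
    **spec_overrides,
) -> LabeledDatasetPair:
    """Moment time-courses from the three two-gene interaction classes.

    ``n_per_model`` independent re-estimates per class: each instance
    re-runs the stochastic simulation of the same model, so instances
    differ only through simulation randomness (set ``rate_jitter`` > 0
    to additionally jitter the rates log-normally per instance).  Gene-A
    courses go to X, gene-B to Y; pairing ids link the two genes of an
    instance.
    """
    _check_size_mode(size_mode)
    if n_per_model < 1:
        raise ValueError("n_per_model must be >= 1")
    rng = np.random.default_rng(seed)

    X_items, Y_items, lab_X, lab_Y, pids = [], [], [], [], []
    pid = 0
    for model in _MODEL_CLASSES:
        count = n_per_model
        if size_mode == "random":
            count = int(rng.integers(2, n_per_model + 1))
        for _ in range(count):
            jit = rng.lognormal(0.0, rate_jitter, size=4)
            spec = default_two_gene_spec(
                model,
                n_trajectories=n_trajectories,
                birth_A=4.0 * jit[0],
                birth_B=4.0 * jit[1],
                gamma_A=0.25 * jit[2],
                gamma_B=0.25 * jit[3],
                **spec_overrides,
            )
            sim_seed = int(rng.integers(0, 2**31 - 1))
            mom_a, mom_b = simulate_two_gene_model(spec, sim_seed)
            X_items.append(mom_a)
            Y_items.append(mom_b)
            lab_X.append(_LABELS_X[model])
            lab_Y.append(_LABELS_Y[model])
            pids.append(pid)
            pid += 1
    pids = np.array(pids)
    return LabeledDatasetPair(
        X_items,
        Y_items,
        np.array(lab_X),
        np.array(lab_Y),
        pids,
        pids.copy(),
        problem_tag="two_gene",
        seed=seed,
        meta={"n_trajectories": n_trajectories, "model_classes": list(_MODEL_CLASSES)},
    )
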