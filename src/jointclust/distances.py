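"""Similarity and association distance matrices and their block assembly.

Similarity distances live within a dataset (Lp distances between feature
vectors).  Association distances live between the two datasets and are
built from statistics of interaction: ``eps + 1 - p_KS`` (same-distribution
evidence), ``eps + 1 - |spearman rho|`` (monotone correlation), and
``eps + mean Granger p`` over the three moment rows (directed regulation).
``assemble`` stacks the triplet into the (m+n)-square block matrix
[[sX*dX, sXY*dXY], [sXY*dXY', sY*dY]].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import distributions as _dists
from scipy.stats import f as f_dist
from scipy.stats import rankdata

from .features import FeatureMatrix

__all__ = [
    "DistanceTriplet",
    "pairwise_norm_distance",
    "ks_association",
    "spearman_association",
    "granger_association",
    "granger_pvalue",
    "assemble",
    "extract_blocks",
]

DEFAULT_EPS = 1e-9


@dataclass
class DistanceTriplet:
    """(dX, dY, dXY) with Euclidean flags and optional block scale factors."""

    dX: np.ndarray
    dY: np.ndarray
    dXY: np.ndarray
    dX_is_euclidean: bool = True
    dY_is_euclidean: bool = True
    scale_factors: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.dX = np.asarray(self.dX, dtype=float)
        self.dY = np.asarray(self.dY, dtype=float)
        self.dXY = np.asarray(self.dXY, dtype=float)
        for name, d in (("dX", self.dX), ("dY", self.dY)):
            if d.ndim != 2 or d.shape[0] != d.shape[1]:
                raise ValueError(f"{name} must be square")
            if not np.allclose(d, d.T):
                raise ValueError(f"{name} must be symmetric")
            if np.any(np.diag(d) != 0):
                raise ValueError(f"{name} must have zero diagonal")
            if np.any(d < 0):
                raise ValueError(f"{name} must be nonnegative")
        if self.dXY.shape != (self.dX.shape[0], self.dY.shape[0]):
            raise ValueError("dXY must be m x n")
        if np.any(self.dXY < 0):
            raise ValueError("dXY must be nonnegative")
        if not np.any(self.dXY > 0):
            raise ValueError("association distance must not be identically zero")
        if any(s <= 0 for s in self.scale_factors):
            raise ValueError("scale factors must be positive")

    @property
    def m(self) -> int:
        return self.dX.shape[0]

    @property
    def n(self) -> int:
        return self.dY.shape[0]


def pairwise_norm_distance(features: FeatureMatrix, p: float = 2.0) -> np.ndarray:
    """Lp distance matrix between feature rows (Euclidean iff p = 2)."""
    if p < 1:
        raise ValueError("p must be >= 1")
    vals = features.values
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite features")
    d = cdist(vals, vals, metric="minkowski", p=p)
    # enforce exact symmetry / zero diagonal against fp round-off
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return d


# ---------------------------------------------------------------------------
# association distances
# ---------------------------------------------------------------------------

def _ks_p_matrix(X_samples: Sequence[np.ndarray], Y_samples: Sequence[np.ndarray]) -> np.ndarray:
    """Two-sample KS p-values for all pairs, asymptotic mode.

    Matches scipy.stats.ks_2samp(method='asymp'): the statistic is the max
    ECDF gap over the pooled points and p = kstwo.sf(d, round(m*n/(m+n))).
    """
    xs = [np.sort(np.asarray(s, dtype=float)) for s in X_samples]
    ys = [np.sort(np.asarray(s, dtype=float)) for s in Y_samples]
    for s in xs + ys:
        if s.size < 2:
            raise ValueError("KS needs at least 2 observations per sample")
    D = np.empty((len(xs), len(ys)))
    for i, x in enumerate(xs):
        nx = x.size
        for j, y in enumerate(ys):
            ny = y.size
            pooled = np.concatenate([x, y])
            Fx = np.searchsorted(x, pooled, side="right") / nx
            Fy = np.searchsorted(y, pooled, side="right") / ny
            D[i, j] = np.abs(Fx - Fy).max()
    sizes = np.array([[x.size * y.size / (x.size + y.size) for y in ys] for x in xs])
    en = np.round(sizes).astype(int)
    P = np.empty_like(D)
    for n_eff in np.unique(en):
        mask = en == n_eff
        P[mask] = _dists.kstwo.sf(np.clip(D[mask], 0, 1), int(n_eff))
    return np.clip(P, 0.0, 1.0)


def ks_association(
    X_samples: Sequence[np.ndarray],
    Y_samples: Sequence[np.ndarray],
    eps: float = DEFAULT_EPS,
) -> np.ndarray:
    """Association distance ``eps + 1 - p_KS`` for every (x, y) pair."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    return eps + 1.0 - _ks_p_matrix(X_samples, Y_samples)


def spearman_association(
    X_samples: Sequence[np.ndarray],
    Y_samples: Sequence[np.ndarray],
    eps: float = DEFAULT_EPS,
) -> np.ndarray:
    """Association distance ``eps + 1 - |spearman rho|`` for paired samples.

    Vectorized as the Pearson correlation of rank-transformed samples.
    A constant sample (undefined rho) yields the maximal distance
    ``eps + 1`` with a warning.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    X = np.vstack([np.asarray(s, dtype=float) for s in X_samples])
    Y = np.vstack([np.asarray(s, dtype=float) for s in Y_samples])
    if X.shape[1] != Y.shape[1]:
        raise ValueError("samples must be paired (equal length)")
    n = X.shape[1]

    def _standardized_ranks(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        R = np.apply_along_axis(rankdata, 1, M)
        R = R - R.mean(axis=1, keepdims=True)
        norms = np.sqrt((R**2).sum(axis=1))
        degenerate = norms == 0
        norms[degenerate] = 1.0
        return R / norms[:, None], degenerate

    Rx, degx = _standardized_ranks(X)
    Ry, degy = _standardized_ranks(Y)
    if degx.any() or degy.any():
        warnings.warn(
            "constant sample(s): Spearman undefined, distance set to eps+1",
            stacklevel=2,
        )
    rho = np.clip(Rx @ Ry.T, -1.0, 1.0)
    rho[degx, :] = 0.0
    rho[:, degy] = 0.0
    return eps + 1.0 - np.abs(rho)


def granger_pvalue(x: np.ndarray, y: np.ndarray, lag: int = 1) -> float:
    """p-value of the F-test that x does not Granger-cause y.

    Restricted model: y_t on its own ``lag`` lags; unrestricted adds the
    lags of x; the ssr F-test compares them (identical to the ssr_ftest of
    standard Granger-causality implementations).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    T = y.size
    if T - lag <= lag + 2:
        raise ValueError("series too short for the requested lag")
    Yt = y[lag:]
    nobs = Yt.size
    lags_y = np.column_stack([y[lag - k - 1 : T - k - 1] for k in range(lag)])
    lags_x = np.column_stack([x[lag - k - 1 : T - k - 1] for k in range(lag)])
    ones = np.ones((nobs, 1))
    Xr = np.hstack([lags_y, ones])
    Xu = np.hstack([lags_y, lags_x, ones])
    ssr_r = _ssr(Xr, Yt)
    ssr_u = _ssr(Xu, Yt)
    dfd = nobs - 2 * lag - 1
    if ssr_u <= 0 or dfd <= 0:
        return 1.0
    F = (ssr_r - ssr_u) / lag / (ssr_u / dfd)
    if not np.isfinite(F) or F < 0:
        return 1.0
    return float(f_dist.sf(F, lag, dfd))


def _ssr(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def granger_association(
    X_timecourses: Sequence[np.ndarray],
    Y_timecourses: Sequence[np.ndarray],
    eps: float = DEFAULT_EPS,
    lag: int = 1,
    direction: str = "either",
) -> np.ndarray:
    """Association distance ``eps + mean_w p_G`` over the moment rows.

    Each item is a 3 x T moment time-course; rows are first-differenced
    for stationarity.  ``direction='either'`` takes, per moment, the
    minimum p over both causal directions (the null is that neither
    series Granger-causes the other); ``'x_to_y_only'`` tests only
    x -> y.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if direction not in ("either", "x_to_y_only"):
        raise ValueError(f"unknown direction {direction!r}")
    Xd = [np.diff(np.asarray(tc, dtype=float), axis=1) for tc in X_timecourses]
    Yd = [np.diff(np.asarray(tc, dtype=float), axis=1) for tc in Y_timecourses]
    n_mom = Xd[0].shape[0]
    out = np.empty((len(Xd), len(Yd)))
    for i, xd in enumerate(Xd):
        for j, yd in enumerate(Yd):
            ps = []
            for w in range(n_mom):
                p_xy = granger_pvalue(xd[w], yd[w], lag)
                if direction == "either":
                    p_yx = granger_pvalue(yd[w], xd[w], lag)
                    ps.append(min(p_xy, p_yx))
                else:
                    ps.append(p_xy)
            out[i, j] = eps + float(np.mean(ps))
    return out


# ---------------------------------------------------------------------------
# block assembly
# ---------------------------------------------------------------------------

def assemble(triplet: DistanceTriplet) -> np.ndarray:
    """Stack the scaled triplet into the (m+n)-square block distance matrix."""
    sX, sY, sXY = triplet.scale_factors
    top = np.hstack([sX * triplet.dX, sXY * triplet.dXY])
    bottom = np.hstack([sXY * triplet.dXY.T, sY * triplet.dY])
    D = np.vstack([top, bottom])
    np.fill_diagonal(D, 0.0)
    return D


def extract_blocks(D: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Inverse of assemble (for scale factors 1): (dX, dY, dXY)."""
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1] or m >= D.shape[0]:
        raise ValueError("invalid block matrix or split index")
    return D[:m, :m], D[m:, m:], D[:m, m:]
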