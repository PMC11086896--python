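"""Order-preserving qualitative Euclidean embedding (qEE) of a distance triplet.

The assembled block distance of two disjoint datasets is generally not a
Euclidean distance.  Shifting every squared off-diagonal entry by one
constant ``c3 * zeta`` preserves the ordering of distances exactly, and for
a large enough shift the matrix passes the Schoenberg criterion (the
double-centered matrix of -1/2 squared distances is positive semidefinite)
and therefore embeds isometrically in Euclidean space.  ``zeta`` is sized
from a Gersgorin-style bound on the anchored cross-Gram terms, and the
constant search doubles ``(c1, c2)`` (with ``c3 = 2 + c1 + c2``) until the
criterion holds.  Coordinates then follow from classical MDS on the full
nonnegative spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distances import DistanceTriplet, assemble

__all__ = [
    "EmbeddingConstants",
    "JointDistance",
    "EmbeddingCoordinates",
    "schoenberg_is_euclidean",
    "compute_zeta",
    "find_constants",
    "build_joint_distance",
    "embed_coordinates",
    "euclideanize_similarity",
    "qee_transform",
]

DEFAULT_TOL = 1e-8
MAX_ITERATIONS = 64


@dataclass
class EmbeddingConstants:
    c1: float
    c2: float
    c3: float
    zeta: float
    anchor: str  # "x1" or "y1"
    iterations_used: int
    schoenberg_min_eigenvalue: float = float("nan")

    def __post_init__(self) -> None:
        if self.zeta < 0:
            raise ValueError("zeta must be nonnegative")
        if abs(2 + self.c1 + self.c2 - self.c3) > 1e-9 * max(1.0, abs(self.c3)):
            raise ValueError("constants must satisfy 2 + c1 + c2 - c3 = 0")

    @property
    def shift(self) -> float:
        return self.c3 * self.zeta


@dataclass
class JointDistance:
    lambda_matrix: np.ndarray
    constants: EmbeddingConstants
    origin_included: bool
    item_ids: list[str]

    def without_origin(self) -> np.ndarray:
        if not self.origin_included:
            return self.lambda_matrix
        return self.lambda_matrix[:-1, :-1]


@dataclass
class EmbeddingCoordinates:
    coords: np.ndarray
    eigenvalue_spectrum: np.ndarray
    item_ids: list[str]


def _double_centered_gram(D: np.ndarray) -> np.ndarray:
    """B = -1/2 J (D o D) J with J the centering projector."""
    D2 = D * D
    row = D2.mean(axis=1, keepdims=True)
    col = D2.mean(axis=0, keepdims=True)
    tot = D2.mean()
    return -0.5 * (D2 - row - col + tot)


def _check_distance_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(D < 0):
        raise ValueError("distance matrix must be nonnegative")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must have zero diagonal")
    return D


def schoenberg_is_euclidean(D: np.ndarray, tol: float = DEFAULT_TOL) -> bool:
    """Schoenberg criterion: D embeds in Euclidean space iff the
    double-centered -1/2 D^2 matrix is PSD (up to -tol relative)."""
    D = _check_distance_matrix(D)
    w = np.linalg.eigvalsh(_double_centered_gram(D))
    scale = max(w[-1], 1e-300)
    return bool(w[0] >= -tol * scale)


def _schoenberg_min_eig(D: np.ndarray) -> tuple[float, float]:
    w = np.linalg.eigvalsh(_double_centered_gram(D))
    return float(w[0]), float(max(w[-1], 1e-300))


def compute_zeta(
    triplet: DistanceTriplet, mode: str = "gershgorin"
) -> tuple[float, str]:
    """Shift scale from the anchored cross-Gram terms.

    With anchor a = x1 (when dX is Euclidean; y1 when only dY is), the
    anchored Gram term for (x, y) is
    ``g = (d_sim(x, a)^2 + d_cross(a, y)^2 - d_cross(x, y)^2) / 2``.
    ``mode='gershgorin'`` (default) returns the larger of the maximal row
    sum and maximal column sum of |g| (a Gersgorin radius of the block);
    ``'max'`` returns max |g| and ``'sum'`` the total sum.
    """
    if mode not in ("gershgorin", "max", "sum"):
        raise ValueError(f"unknown zeta mode {mode!r}")
    if triplet.dX_is_euclidean:
        anchor = "x1"
        d_sim = triplet.dX[:, 0]  # d(x, x1) for all x
        d_anchor_cross = triplet.dXY[0, :]  # d(x1, y) for all y
        cross = triplet.dXY
    elif triplet.dY_is_euclidean:
        anchor = "y1"
        d_sim = triplet.dY[:, 0]  # d(y, y1)
        d_anchor_cross = triplet.dXY[:, 0]  # d(x, y1)
        cross = triplet.dXY.T  # rows indexed by y
    else:
        raise ValueError(
            "neither similarity distance is Euclidean; "
            "route the non-Euclidean one through euclideanize_similarity first"
        )
    g = 0.5 * np.abs(
        d_sim[:, None] ** 2 + d_anchor_cross[None, :] ** 2 - cross**2
    )
    if mode == "max":
        zeta = float(g.max())
    elif mode == "sum":
        zeta = float(g.sum())
    else:
        zeta = float(max(g.sum(axis=1).max(), g.sum(axis=0).max()))
    return zeta, anchor


def _lambda_from_shift(
    D: np.ndarray, shift: float, magnitudes: np.ndarray | None
) -> np.ndarray:
    """Off-diagonal Lambda = sqrt(d^2 + shift); optional origin row/col
    with Lambda(a, o)^2 = |a|^2 + shift."""
    L = np.sqrt(D * D + shift)
    np.fill_diagonal(L, 0.0)
    if magnitudes is not None:
        o = np.sqrt(np.asarray(magnitudes, dtype=float) ** 2 + shift)
        L = np.block([[L, o[:, None]], [o[None, :], np.zeros((1, 1))]])
    return L


def find_constants(
    triplet: DistanceTriplet,
    init: str = "fixed",
    seed: int | None = None,
    tol: float = DEFAULT_TOL,
    zeta_mode: str = "gershgorin",
    magnitudes: np.ndarray | None = None,
    max_iterations: int = MAX_ITERATIONS,
) -> EmbeddingConstants:
    """Doubling search for (c1, c2, c3) making the shifted matrix Euclidean.

    Initialization is (1/2, 2) for ``init='fixed'`` or uniform in (0, 1)
    for ``init='random'``; c3 = 2 + c1 + c2 throughout.  While the
    Schoenberg check fails: c1 <- c2, c2 <- 2 c1.  When ``magnitudes`` are
    given the origin row (squared distance |a|^2 + c3 zeta) is part of the
    checked matrix.
    """
    if init == "fixed":
        c1, c2 = 0.5, 2.0
    elif init == "random":
        rng = np.random.default_rng(seed)
        c1, c2 = rng.uniform(0.0, 1.0, size=2)
    else:
        raise ValueError(f"unknown init {init!r}")
    zeta, anchor = compute_zeta(triplet, mode=zeta_mode)
    D = assemble(triplet)

    iterations = 0
    min_eig = float("nan")
    while True:
        iterations += 1
        c3 = 2.0 + c1 + c2
        if iterations > max_iterations:
            raise RuntimeError(
                f"constant search failed after {iterations - 1} iterations "
                f"(next c3={c3:.3g}, zeta={zeta:.3g}, last min eig {min_eig:.3g})"
            )
        L = _lambda_from_shift(D, c3 * zeta, magnitudes)
        min_eig, max_eig = _schoenberg_min_eig(L)
        if min_eig >= -tol * max_eig:
            return EmbeddingConstants(
                c1=c1,
                c2=c2,
                c3=c3,
                zeta=zeta,
                anchor=anchor,
                iterations_used=iterations,
                schoenberg_min_eigenvalue=min_eig,
            )
        c1, c2 = c2, 2.0 * c2


def _default_ids(m: int, n: int, origin: bool) -> list[str]:
    ids = [f"X:{i}" for i in range(m)] + [f"Y:{j}" for j in range(n)]
    if origin:
        ids.append("O:origin")
    return ids


def build_joint_distance(
    triplet: DistanceTriplet,
    constants: EmbeddingConstants,
    include_origin: bool = False,
    magnitudes: np.ndarray | None = None,
    item_ids: list[str] | None = None,
) -> JointDistance:
    """The joint Euclidean distance Lambda = sqrt(d^2 + c3 zeta).

    With ``include_origin`` an extra point o is appended whose squared
    distance to each item is that item's feature-space squared norm plus
    the shift, encoding magnitudes in the embedding.
    """
    if include_origin and magnitudes is None:
        raise ValueError("include_origin requires per-item magnitudes")
    D = assemble(triplet)
    L = _lambda_from_shift(D, constants.shift, magnitudes if include_origin else None)
    if item_ids is None:
        item_ids = _default_ids(triplet.m, triplet.n, include_origin)
    if len(item_ids) != L.shape[0]:
        raise ValueError("item_ids length mismatch")
    return JointDistance(L, constants, include_origin, list(item_ids))


def embed_coordinates(
    joint: JointDistance, tol: float = DEFAULT_TOL
) -> EmbeddingCoordinates:
    """Classical MDS coordinates reproducing the joint distance.

    Eigenvalues of the double-centered Gram matrix in [-tol*max, 0] are
    clamped to zero; a more negative one means the Schoenberg criterion
    is violated and is an error.
    """
    L = joint.lambda_matrix
    B = _double_centered_gram(L)
    w, V = np.linalg.eigh(B)
    w = w[::-1].copy()
    V = V[:, ::-1]
    scale = max(w[0], 1e-300)
    if w[-1] < -tol * scale:
        raise ValueError(
            f"negative eigenvalue {w[-1]:.3g} below tolerance: matrix is not Euclidean"
        )
    w[w < tol * scale] = 0.0  # clamp fp-noise eigenvalues on both sides
    keep = w > 0
    coords = V[:, keep] * np.sqrt(w[keep])
    return EmbeddingCoordinates(coords, w, list(joint.item_ids))


def _line_placeholder(n: int, scale: float = 1.0) -> np.ndarray:
    """Distances of n evenly spaced points on a line: a deterministic
    Euclidean placeholder carrying no information about the data."""
    pos = scale * np.arange(n, dtype=float)
    return np.abs(pos[:, None] - pos[None, :])


def euclideanize_similarity(
    d_nonmetric: np.ndarray,
    placeholder: np.ndarray | str = "auto",
    tol: float = DEFAULT_TOL,
    zeta_mode: str = "gershgorin",
) -> np.ndarray:
    """Order-equivalent Euclidean version of a non-Euclidean similarity.

    The dataset is embedded jointly with a relabeled duplicate of itself:
    the placeholder Euclidean distance plays the similarity role on the
    original copy, and the non-Euclidean distance supplies both the
    duplicate-block similarity and the cross-block association.  The
    restriction of the resulting joint Euclidean distance to the duplicate
    block is returned: its squared entries equal the squared input plus a
    constant, so distance ordering is preserved exactly.
    """
    d = _check_distance_matrix(d_nonmetric)
    n = d.shape[0]
    if isinstance(placeholder, str):
        if placeholder != "auto":
            raise ValueError(f"unknown placeholder {placeholder!r}")
        off = d[~np.eye(n, dtype=bool)]
        scale = float(off.mean() / max(n - 1, 1)) if off.size else 1.0
        placeholder = _line_placeholder(n, scale if scale > 0 else 1.0)
    else:
        placeholder = np.asarray(placeholder, dtype=float)
        if not schoenberg_is_euclidean(placeholder, tol):
            raise ValueError("placeholder distance must be Euclidean")
    cross = d.copy()
    if not np.any(cross > 0):
        raise ValueError("input distance is identically zero")
    trip = DistanceTriplet(
        dX=placeholder,
        dY=d,
        dXY=cross,
        dX_is_euclidean=True,
        dY_is_euclidean=False,
    )
    constants = find_constants(trip, tol=tol, zeta_mode=zeta_mode)
    joint = build_joint_distance(trip, constants)
    return joint.lambda_matrix[n:, n:]


def qee_transform(
    triplet: DistanceTriplet,
    init: str = "fixed",
    seed: int | None = None,
    tol: float = DEFAULT_TOL,
    zeta_mode: str = "gershgorin",
    include_origin: bool = False,
    magnitudes: np.ndarray | None = None,
    item_ids: list[str] | None = None,
) -> tuple[JointDistance, EmbeddingCoordinates]:
    """Convenience wrapper: constant search, joint distance, coordinates.

    A triplet whose similarity distances are both flagged non-Euclidean is
    first routed through ``euclideanize_similarity`` on the X block.
    """
    if not (triplet.dX_is_euclidean or triplet.dY_is_euclidean):
        dX_eucl = euclideanize_similarity(triplet.dX, tol=tol, zeta_mode=zeta_mode)
        triplet = DistanceTriplet(
            dX=dX_eucl,
            dY=triplet.dY,
            dXY=triplet.dXY,
            dX_is_euclidean=True,
            dY_is_euclidean=triplet.dY_is_euclidean,
            scale_factors=triplet.scale_factors,
        )
    constants = find_constants(
        triplet,
        init=init,
        seed=seed,
        tol=tol,
        zeta_mode=zeta_mode,
        magnitudes=magnitudes if include_origin else None,
    )
    joint = build_joint_distance(
        triplet, constants, include_origin, magnitudes, item_ids
    )
    coords = embed_coordinates(joint, tol=tol)
    return joint, coords
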