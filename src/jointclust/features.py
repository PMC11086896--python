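"""Feature transformations turning raw items into fixed-length vectors.

Similarity distances within a dataset are Euclidean (or Lp) distances
between these feature vectors: histogram heights for distribution samples,
empirical CDF values on a common grid for correlated samples, and min-max
normalized moment time-courses for the stochastic gene models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "FeatureMatrix",
    "histogram_features",
    "ecdf_features",
    "minmax_timecourse",
]


@dataclass
class FeatureMatrix:
    values: np.ndarray  # items x feature-dim
    transform_tag: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")


def histogram_features(
    samples: Sequence[np.ndarray], n_bins: int = 10, norm: str = "count"
) -> FeatureMatrix:
    """Histogram heights over each sample's own range.

    ``norm`` selects the height scale: ``'count'`` (default) uses raw bin
    counts, ``'mass'`` the fraction of observations per bin, and
    ``'density'`` a density normalization (heights scale with 1/range).
    Count heights keep the similarity distances on the scale of the sample
    size, so they dominate the [0, 1]-bounded association distances in the
    assembled matrix; the density scale ties feature magnitude to the
    sample range, which smears heavy-tailed families across feature space.

    A constant sample has zero range; its whole mass falls into a single
    bin (degenerate-bin rule) and a warning is emitted.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if norm not in ("count", "mass", "density"):
        raise ValueError(f"unknown histogram norm {norm!r}")
    rows = []
    for i, s in enumerate(samples):
        s = np.asarray(s, dtype=float)
        if s.size < 2:
            raise ValueError(f"sample {i} has fewer than 2 observations")
        if np.ptp(s) == 0:
            warnings.warn(
                f"sample {i} is constant; histogram collapses to one bin",
                stacklevel=2,
            )
        heights, _ = np.histogram(s, bins=n_bins, density=(norm == "density"))
        if norm == "mass":
            heights = heights / s.size
        rows.append(heights.astype(float))
    return FeatureMatrix(np.vstack(rows), "histogram")


def ecdf_features(
    samples: Sequence[np.ndarray], grid_size: int = 100
) -> FeatureMatrix:
    """Empirical CDF of each sample evaluated on a shared grid.

    The grid spans the pooled range of all samples, so feature vectors are
    comparable across samples; each row is nondecreasing with values in
    [0, 1].
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty sample")
    lo = min(a.min() for a in arrays)
    hi = max(a.max() for a in arrays)
    grid = np.linspace(lo, hi, grid_size)
    rows = [
        np.searchsorted(np.sort(a), grid, side="right") / a.size for a in arrays
    ]
    return FeatureMatrix(np.vstack(rows), "ecdf")


def minmax_timecourse(timecourses: Sequence[np.ndarray]) -> FeatureMatrix:
    """Min-max normalize each moment row of a 3 x T time-course, flatten.

    Each of the stacked moment rows (mean, variance, skewness) is rescaled
    to [0, 1] by its own range; a constant row maps to all zeros (warning).
    """
    rows = []
    for i, tc in enumerate(timecourses):
        tc = np.asarray(tc, dtype=float)
        if tc.ndim != 2 or tc.shape[1] < 2:
            raise ValueError(f"time-course {i} must be 2-d with >= 2 time points")
        scaled = np.empty_like(tc)
        for r in range(tc.shape[0]):
            rng_ = np.ptp(tc[r])
            if rng_ == 0:
                warnings.warn(
                    f"time-course {i}, moment row {r} is constant; mapped to zeros",
                    stacklevel=2,
                )
                scaled[r] = 0.0
            else:
                scaled[r] = (tc[r] - tc[r].min()) / rng_
        rows.append(scaled.ravel())
    return FeatureMatrix(np.vstack(rows), "minmax_timecourse")
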