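"""Regular-space clustering for diverse seed-structure selection.

A single pass over the structures in input order: a structure becomes a new
cluster center iff its Euclidean distance in feature space to every existing
center exceeds the threshold ``d_min``.  The centers are therefore mutually
separated by more than ``d_min`` and every structure lies within ``d_min``
of at least one center — a cheap way to pick a handful of well-spread seed
conformations to start short simulations from.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .features import FeatureMatrix


@dataclass
class ClusterResult:
    """Cluster centers (structure indices, input order) and assignments."""

    center_indices: np.ndarray
    assignments: np.ndarray
    d_min: float

    @property
    def n_centers(self) -> int:
        return len(self.center_indices)


def _as_array(matrix) -> np.ndarray:
    if isinstance(matrix, FeatureMatrix):
        return matrix.values
    return np.atleast_2d(np.asarray(matrix, dtype=float))


def regular_space_cluster(matrix, d_min: float) -> ClusterResult:
    """Single-pass regular-space clustering with strict ``>`` at the threshold.

    The first structure is always a center.  Assignments map every structure
    to its nearest center (by Euclidean distance over the feature columns).
    """
    X = _as_array(matrix)
    if d_min < 0:
        raise ValueError("d_min must be >= 0")
    if X.shape[0] < 1:
        raise ValueError("need at least one structure")
    centers = [0]
    for i in range(1, X.shape[0]):
        d = np.sqrt(np.sum((X[centers] - X[i]) ** 2, axis=1))
        if np.all(d > d_min):
            centers.append(i)
    center_idx = np.asarray(centers, dtype=int)
    d_all = np.sqrt(
        np.sum((X[:, None, :] - X[center_idx][None, :, :]) ** 2, axis=2)
    )
    assignments = np.argmin(d_all, axis=1)
    return ClusterResult(center_indices=center_idx, assignments=assignments, d_min=float(d_min))


def suggest_d_min(
    matrix,
    target_centers: tuple[int, int] = (5, 20),
    max_iter: int = 30,
) -> tuple[float, int]:
    """Bisection on ``d_min`` until the center count falls in a target range.

    Guidance for seeding short simulations is a handful of centers (5-20 by
    default).  Returns ``(d_min, achieved_count)``; if the target cannot be
    reached (fewer distinct structures than the lower bound) the best-effort
    threshold is returned with a warning.
    """
    lo_target, hi_target = target_centers
    if lo_target > hi_target or lo_target < 1:
        raise ValueError("target_centers must be a non-empty (lo, hi) range")
    X = _as_array(matrix)
    n_distinct = len(np.unique(X, axis=0))
    # center count is non-increasing in d_min: bisect on the threshold
    d_lo = 0.0  # yields n_distinct centers
    span = np.linalg.norm(X.max(axis=0) - X.min(axis=0))
    d_hi = span if span > 0 else 1.0  # yields 1 center
    if n_distinct < lo_target:
        warnings.warn(
            f"only {n_distinct} distinct structures; target of at least "
            f"{lo_target} centers is unreachable"
        )
        return 0.0, regular_space_cluster(X, 0.0).n_centers
    best = (d_lo, regular_space_cluster(X, d_lo).n_centers)
    for _ in range(max_iter):
        mid = 0.5 * (d_lo + d_hi)
        count = regular_space_cluster(X, mid).n_centers
        if lo_target <= count <= hi_target:
            return mid, count
        if count > hi_target:
            d_lo = mid  # too many centers -> raise threshold
        else:
            d_hi = mid
        best = (mid, count)
    warnings.warn(
        f"bisection did not land in [{lo_target}, {hi_target}] after "
        f"{max_iter} iterations; returning d_min={best[0]:.4g} with "
        f"{best[1]} centers"
    )
    return best
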