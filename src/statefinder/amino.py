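"""Mutual-information CV pruning (AMINO-style redundancy removal).

CVs picked purely by variance ranking are heavily redundant: if the distance
between residues m and n made the cut, the distances between their sequence
neighbours usually did too.  This module removes that redundancy by
clustering CVs under a mutual-information dissimilarity,

    D(X, Y) = 1 - I(X; Y) / H(X, Y)  in [0, 1],

(0 for identical signals, 1 for independent ones) and keeping one medoid CV
per cluster.  The number of clusters is chosen automatically with the
distortion-jump criterion.

Mutual information is the plug-in estimate on equal-width histograms of the
pooled frames: redundancy is a static property of the CV set, so trajectory
boundaries play no role here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import entropy as _scipy_entropy
from sklearn.metrics import mutual_info_score

from .structure_io import TimeSeries

_LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

@dataclass
class DiscretizedSeries:
    """Per-frame integer bin labels for every CV, plus the bin edges."""

    labels: np.ndarray  # (n_frames_total, n_cvs) int
    n_bins: int
    edges: list[np.ndarray]
    column_names: list[str]


def discretize(ts: TimeSeries, n_bins: int = 20) -> DiscretizedSeries:
    """Equal-width binning over the pooled frames of all trajectories.

    Bins span [min, max] per CV; the last bin is right-closed so the maximum
    falls in bin ``n_bins - 1``.  A constant CV has zero range: all frames go
    to bin 0 with a warning.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    X = ts.pooled()
    labels = np.zeros(X.shape, dtype=np.int32)
    edges = []
    for j in range(X.shape[1]):
        lo, hi = X[:, j].min(), X[:, j].max()
        if hi <= lo:
            warnings.warn(
                f"CV {ts.column_names[j]!r} is constant; all frames in bin 0"
            )
            edges.append(np.linspace(lo, lo + 1.0, n_bins + 1))
            continue
        e = np.linspace(lo, hi, n_bins + 1)
        width = (hi - lo) / n_bins
        lab = np.floor((X[:, j] - lo) / width).astype(np.int32)
        labels[:, j] = np.minimum(lab, n_bins - 1)
        edges.append(e)
    return DiscretizedSeries(
        labels=labels, n_bins=n_bins, edges=edges, column_names=list(ts.column_names)
    )


# ---------------------------------------------------------------------------
# Information measures (plug-in estimates, in bits)
# ---------------------------------------------------------------------------

def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information I(X;Y) in bits from empirical frequencies."""
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    return float(mutual_info_score(x, y) / _LN2)


def joint_entropy(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in joint entropy H(X,Y) in bits."""
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if np.issubdtype(x.dtype, np.integer) and np.issubdtype(y.dtype, np.integer):
        joint = x.astype(np.int64) * (np.int64(y.max()) + 1) + y
    else:
        _, joint = np.unique(np.stack([x, y], axis=1), axis=0, return_inverse=True)
    _, counts = np.unique(joint, return_counts=True)
    return float(_scipy_entropy(counts, base=2))


def mi_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Normalized MI dissimilarity D = 1 - I(X;Y)/H(X,Y), in [0, 1].

    Degenerate case: two constant signals carry no information at all
    (H(X,Y) = 0); they are treated as identical, D = 0, with a warning.
    """
    h = joint_entropy(x, y)
    if h <= 0.0:
        warnings.warn("both signals constant (H = 0); defining D = 0")
        return 0.0
    d = 1.0 - mutual_information(x, y) / h
    if d < 1e-9:  # identical signals up to floating-point noise
        return 0.0
    return float(min(d, 1.0))


def mi_distance_matrix(disc: DiscretizedSeries) -> np.ndarray:
    """Symmetric pairwise MI-distance matrix over CVs (zero diagonal)."""
    n = disc.labels.shape[1]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = mi_distance(disc.labels[:, i], disc.labels[:, j])
    return D


# ---------------------------------------------------------------------------
# k-medoids under the MI distance
# ---------------------------------------------------------------------------

def _kmedoidspp_init(D: np.ndarray, k: int, rng: np.random.Generator) -> list[int]:
    """k-medoids++ seeding: spread initial medoids by D^2-weighted sampling."""
    n = D.shape[0]
    medoids = [int(rng.integers(n))]
    for _ in range(1, k):
        d2 = np.min(D[:, medoids], axis=1) ** 2
        total = d2.sum()
        if total <= 0:
            # all remaining points coincide with a medoid; pick any non-medoid
            choices = [i for i in range(n) if i not in medoids]
            medoids.append(int(rng.choice(choices)))
            continue
        medoids.append(int(rng.choice(n, p=d2 / total)))
    return medoids


def _pam(D: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 100):
    """PAM-style swap local search; returns (medoids, cost)."""
    n = D.shape[0]
    medoids = _kmedoidspp_init(D, k, rng)
    cost = np.min(D[:, medoids], axis=1).sum()
    for _ in range(max_iter):
        improved = False
        for mi in range(k):
            for candidate in range(n):
                if candidate in medoids:
                    continue
                trial = list(medoids)
                trial[mi] = candidate
                trial_cost = np.min(D[:, trial], axis=1).sum()
                if trial_cost < cost - 1e-15:
                    medoids, cost = trial, trial_cost
                    improved = True
        if not improved:
            break
    return sorted(medoids), cost


# ---------------------------------------------------------------------------
# AMINO reduction
# ---------------------------------------------------------------------------

@dataclass
class AminoResult:
    """Outcome of the redundancy reduction."""

    selected: list[str]
    k: int
    distance_matrix: np.ndarray
    distortions: np.ndarray  # distortion d_k for k = 1..k_max
    jumps: np.ndarray  # transformed-distortion jumps used to pick k
    medoid_indices: list[int]
    assignments: np.ndarray  # cluster id per CV (index into medoid_indices)


def amino_reduce(
    ts: TimeSeries,
    k_max: int = 20,
    n_bins: int = 20,
    seed: int = 0,
) -> AminoResult:
    """Prune redundant CVs, keeping one medoid per correlated group.

    For each candidate ``k`` in 1..k_max a k-medoid clustering under the MI
    distance is run (seeded k-medoids++ + PAM swaps, deterministic given
    ``seed``); the distortion d_k is the mean squared MI-distance of each CV
    to its nearest medoid.  ``k`` is chosen by the distortion-jump criterion
    on the inverse-transformed curve, ``argmax_k d_k^{-1} - d_{k-1}^{-1}``
    (with ``d_0^{-1} := 0``); a k whose medoids reproduce every CV exactly
    (d_k = 0) ends the scan with an infinite jump.

    Note: the jump criterion needs ``k_max`` meaningfully smaller than the
    number of CVs when CVs are noisy near-duplicates — at k = n_CVs the
    distortion is identically zero and the criterion degenerates.
    """
    n_cvs = ts.n_cvs
    if n_cvs < 2:
        raise ValueError("amino_reduce requires at least 2 CVs")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if k_max > n_cvs:
        warnings.warn(f"k_max={k_max} exceeds {n_cvs} CVs; clamping")
        k_max = n_cvs

    disc = discretize(ts, n_bins=n_bins)
    D = mi_distance_matrix(disc)
    rng = np.random.default_rng(seed)

    distortions = np.empty(k_max)
    medoids_by_k: list[list[int]] = []
    for k in range(1, k_max + 1):
        medoids, _ = _pam(D, k, rng)
        d2 = np.min(D[:, medoids], axis=1) ** 2
        distortions[k - 1] = d2.mean()
        medoids_by_k.append(medoids)
        if distortions[k - 1] == 0.0:
            # perfect reproduction; larger k cannot be justified
            distortions = distortions[:k]
            break

    with np.errstate(divide="ignore"):
        inv = np.where(distortions > 0, 1.0 / distortions, np.inf)
    jumps = np.diff(np.concatenate([[0.0], inv]))
    jumps = np.where(np.isnan(jumps), 0.0, jumps)
    best_k = int(np.argmax(jumps)) + 1

    medoids = medoids_by_k[best_k - 1]
    assignments = np.argmin(D[:, medoids], axis=1)
    return AminoResult(
        selected=[ts.column_names[m] for m in medoids],
        k=best_k,
        distance_matrix=D,
        distortions=distortions,
        jumps=jumps,
        medoid_indices=list(medoids),
        assignments=assignments,
    )
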