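"""Pairwise-distance feature enumeration, CoV ranking, and RMSD filtering.

The feature-selection stage turns a structurally diverse ensemble into a
coarse set of informative collective variables: pairwise atom distances
whose variation across the ensemble is large.  Features are ranked by the
coefficient of variance, defined here as variance/mean (units: Angstrom),
and the top few percent are kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .selection import AtomSelection
from .structure_io import StructureEnsemble, superpose


@dataclass(frozen=True)
class FeatureSpec:
    """One pairwise-distance feature between two schema atoms."""

    atom_i: int
    atom_j: int
    label: str

    def __post_init__(self):
        if not self.atom_i < self.atom_j:
            raise ValueError("FeatureSpec requires atom_i < atom_j")


@dataclass
class FeatureMatrix:
    """Structures x features distance matrix (Angstrom)."""

    values: np.ndarray
    specs: list[FeatureSpec]
    source_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.specs):
            raise ValueError("values must be (n_structures, n_features)")
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("feature values must be positive and finite")

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.specs]


def _atom_label(atoms: pd.DataFrame, i: int) -> str:
    row = atoms.iloc[i]
    return f"{row.chain_id}:{row.res_id}:{row.atom_name}"


def select_reference(ensemble: StructureEnsemble) -> int:
    """Index of the structure with the highest mean pLDDT.

    Ties break to the lowest input index.  If B-factors carry no signal at
    all (all zero), a warning is issued and index 0 is returned.
    """
    if ensemble.n_structures == 0:
        raise ValueError("empty ensemble")
    plddt = ensemble.mean_plddt
    if np.all(ensemble.b_factors == 0):
        warnings.warn(
            "all B-factors are zero: no pLDDT information; "
            "falling back to the first structure as reference"
        )
        return 0
    return int(np.argmax(plddt))  # argmax returns the first maximum


def rmsd_filter(
    ensemble: StructureEnsemble,
    reference_index: int,
    cutoff: float,
    fit_selection: AtomSelection | None = None,
) -> tuple[StructureEnsemble, np.ndarray]:
    """Keep structures within ``cutoff`` A RMSD of the reference.

    Superposition removes rigid-body motion before the RMSD is computed, so
    translated/rotated copies of the reference always survive.  The
    reference itself is always kept and input order is preserved.  Returns
    the filtered ensemble and the per-input-structure RMSD values.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    fit_idx = (
        fit_selection.resolve(ensemble.atoms) if fit_selection is not None else None
    )
    reference = ensemble.coords[reference_index]
    rmsds = np.empty(ensemble.n_structures)
    for i in range(ensemble.n_structures):
        _, rmsds[i] = superpose(ensemble.coords[i], reference, fit_idx)
    keep = np.flatnonzero((rmsds <= cutoff) | (np.arange(len(rmsds)) == reference_index))
    return ensemble.subset(keep), rmsds


def enumerate_pair_features(
    atoms: pd.DataFrame,
    selection: AtomSelection | np.ndarray | None = None,
    min_residue_separation: int = 3,
) -> list[FeatureSpec]:
    """All unordered atom pairs from a selection, pruned by sequence distance.

    Pairs closer than ``min_residue_separation`` residues along the chain are
    dropped (they are trivially rigid); pairs across different chains are
    always allowed.
    """
    if selection is None:
        idx = np.arange(len(atoms))
    elif isinstance(selection, AtomSelection):
        idx = selection.resolve(atoms)
    else:
        idx = np.asarray(selection, dtype=int)
    if idx.size < 2:
        raise ValueError("feature enumeration requires at least 2 selected atoms")
    resid = atoms["res_id"].to_numpy()
    chain = atoms["chain_id"].to_numpy()
    specs = []
    for a in range(idx.size):
        for b in range(a + 1, idx.size):
            i, j = int(idx[a]), int(idx[b])
            if chain[i] == chain[j] and abs(resid[i] - resid[j]) < min_residue_separation:
                continue
            label = f"{_atom_label(atoms, i)}-{_atom_label(atoms, j)}"
            specs.append(FeatureSpec(min(i, j), max(i, j), label))
    return specs


def compute_features(
    ensemble: StructureEnsemble, specs: list[FeatureSpec]
) -> FeatureMatrix:
    """Evaluate pairwise distances (A) for every structure."""
    ii = np.array([s.atom_i for s in specs])
    jj = np.array([s.atom_j for s in specs])
    diff = ensemble.coords[:, ii, :] - ensemble.coords[:, jj, :]
    values = np.sqrt(np.sum(diff * diff, axis=2))
    return FeatureMatrix(values=values, specs=list(specs), source_ids=list(ensemble.source_ids))


def feature_stats(matrix: FeatureMatrix) -> pd.DataFrame:
    """Per-feature mean, population variance, and CoV = variance/mean.

    Note the deliberate definition: CoV here is variance/mean (units A), not
    the conventional dimensionless std/mean; ``std_over_mean`` is also
    reported for users who expect the latter.
    """
    mean = matrix.values.mean(axis=0)
    var = matrix.values.var(axis=0)  # population variance (divide by N)
    return pd.DataFrame(
        {
            "label": matrix.labels,
            "mean": mean,
            "variance": var,
            "cov": var / mean,
            "std_over_mean": np.sqrt(var) / mean,
        }
    )


def rank_by_cov(
    matrix: FeatureMatrix,
    top_m: int | None = None,
    use_std: bool = False,
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Restrict a feature matrix to the ``top_m`` highest-CoV features.

    ``top_m`` defaults to ``min(ceil(0.05 * n_features), 200)`` — roughly the
    top 5% of features, capped at a couple of hundred.  Ranking is by CoV
    descending with ties broken by label (lexicographic), making the result
    a deterministic function of the feature set.  Returns the restricted
    matrix and the full ranked stats table.
    """
    if top_m is None:
        top_m = min(int(np.ceil(0.05 * len(matrix.specs))), 200)
    if top_m < 1:
        raise ValueError("top_m must be >= 1")
    stats = feature_stats(matrix)
    key = "std_over_mean" if use_std else "cov"
    order = stats.sort_values(
        [key, "label"], ascending=[False, True], kind="mergesort"
    ).index.to_numpy()
    stats = stats.loc[order].reset_index(drop=True)
    stats["rank"] = np.arange(1, len(stats) + 1)
    if top_m > len(matrix.specs):
        warnings.warn(
            f"top_m={top_m} exceeds the {len(matrix.specs)} available features; "
            "keeping all"
        )
        top_m = len(matrix.specs)
    keep = order[:top_m]
    restricted = FeatureMatrix(
        values=matrix.values[:, keep],
        specs=[matrix.specs[i] for i in keep],
        source_ids=list(matrix.source_ids),
    )
    return restricted, stats
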