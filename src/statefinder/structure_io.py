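"""Structure-ensemble and CV time-series I/O, superposition and RMSD.

Structures are read from PDB files (AlphaFold2 convention: per-atom pLDDT in
the B-factor column).  All structures in an ensemble are harmonized onto a
common atom schema keyed by ``(chain id, residue id, atom name)`` so that
pairwise-distance features are comparable across the ensemble.

Time series are plain-text tabular files (whitespace- or comma-delimited),
one row per frame, one column per CV, with an optional leading ``#`` header
line naming the columns.
"""

from __future__ import annotations

import glob as _glob
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio
from scipy.spatial.transform import Rotation

from .selection import AtomSelection

ATOM_COLUMNS = ["chain_id", "res_id", "res_name", "atom_name"]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class StructureEnsemble:
    """An aligned collection of structures sharing one atom schema.

    Attributes
    ----------
    coords:
        Array of shape ``(n_structures, n_atoms, 3)`` in Angstrom.
    atoms:
        Atom table (one row per schema atom) with columns
        ``chain_id, res_id, res_name, atom_name``.
    b_factors:
        Per-structure, per-atom B-factor values, shape
        ``(n_structures, n_atoms)``.  For AlphaFold2 output these are pLDDT
        scores in [0, 100].
    source_ids:
        Per-structure provenance strings (file name, plus model number for
        multi-model files).
    """

    coords: np.ndarray
    atoms: pd.DataFrame
    b_factors: np.ndarray
    source_ids: list[str]

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.b_factors = np.asarray(self.b_factors, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_structures, n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in ensemble")
        if self.b_factors.shape != self.coords.shape[:2]:
            raise ValueError("b_factors shape must match (n_structures, n_atoms)")
        if len(self.source_ids) != self.n_structures:
            raise ValueError("source_ids length mismatch")

    @property
    def n_structures(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def mean_plddt(self) -> np.ndarray:
        """Per-structure mean B-factor over the schema atoms."""
        return self.b_factors.mean(axis=1)

    def subset(self, structure_indices) -> "StructureEnsemble":
        idx = np.asarray(structure_indices, dtype=int)
        return StructureEnsemble(
            coords=self.coords[idx],
            atoms=self.atoms,
            b_factors=self.b_factors[idx],
            source_ids=[self.source_ids[i] for i in idx],
        )


@dataclass
class TimeSeries:
    """One or more equally-sampled multivariate CV trajectories.

    Trajectories share a column schema but are kept separate: time-lagged
    quantities must never be formed across trajectory boundaries.
    """

    trajectories: list[np.ndarray]
    dt: float = 1.0
    column_names: list[str] = field(default_factory=list)
    traj_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.trajectories = [np.asarray(t, dtype=float) for t in self.trajectories]
        if not self.trajectories:
            raise ValueError("TimeSeries requires at least one trajectory")
        n_cols = self.trajectories[0].shape[1] if self.trajectories[0].ndim == 2 else 1
        fixed = []
        for t in self.trajectories:
            if t.ndim == 1:
                t = t[:, None]
            if t.ndim != 2 or t.shape[1] != n_cols:
                raise ValueError("all trajectories must share the same column schema")
            if t.shape[0] < 2:
                raise ValueError("each trajectory needs at least 2 frames")
            if not np.all(np.isfinite(t)):
                raise ValueError("missing or non-finite values in time series")
            fixed.append(t)
        self.trajectories = fixed
        if not self.column_names:
            self.column_names = [f"cv{i}" for i in range(n_cols)]
        if len(self.column_names) != n_cols:
            raise ValueError("column_names length does not match column count")
        if not self.traj_ids:
            self.traj_ids = [f"traj{i}" for i in range(len(self.trajectories))]

    @property
    def n_cvs(self) -> int:
        return self.trajectories[0].shape[1]

    @property
    def n_frames(self) -> int:
        return sum(t.shape[0] for t in self.trajectories)

    def pooled(self) -> np.ndarray:
        """All frames stacked (static statistics only; order is traj-major)."""
        return np.vstack(self.trajectories)

    def select_columns(self, names) -> "TimeSeries":
        missing = [n for n in names if n not in self.column_names]
        if missing:
            raise KeyError(f"unknown CV columns: {missing}")
        idx = [self.column_names.index(n) for n in names]
        return TimeSeries(
            trajectories=[t[:, idx] for t in self.trajectories],
            dt=self.dt,
            column_names=list(names),
            traj_ids=list(self.traj_ids),
        )


# ---------------------------------------------------------------------------
# PDB ensemble I/O
# ---------------------------------------------------------------------------

def _atom_table(array: struc.AtomArray) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chain_id": array.chain_id.astype(str),
            "res_id": array.res_id.astype(int),
            "res_name": array.res_name.astype(str),
            "atom_name": array.atom_name.astype(str),
        }
    )


def _read_pdb_models(path: str | Path):
    """Yield (source_id, AtomArray) for every MODEL in a PDB file."""
    path = Path(path)
    try:
        pdb_file = pdbio.PDBFile.read(str(path))
        n_models = pdb_file.get_model_count()
        arrays = []
        for m in range(1, n_models + 1):
            arrays.append(pdb_file.get_structure(model=m, extra_fields=["b_factor"]))
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise IOError(f"cannot read PDB file {path}: {exc}") from exc
    for m, array in enumerate(arrays, start=1):
        if np.any(array.ins_code != ""):
            raise ValueError(
                f"{path}: insertion codes are not supported "
                "(AlphaFold2 output never contains them)"
            )
        source_id = path.name if len(arrays) == 1 else f"{path.name}#model{m}"
        yield source_id, array


def load_ensemble(paths, selection: AtomSelection | str) -> StructureEnsemble:
    """Load PDB files into a schema-harmonized :class:`StructureEnsemble`.

    Parameters
    ----------
    paths:
        A list of file paths, or a single glob pattern (expanded and sorted
        for determinism).  Multi-model files are expanded into one structure
        per MODEL record.
    selection:
        Atom selection applied to every structure.  The final schema is the
        intersection of the per-structure selections keyed by
        ``(chain id, residue id, atom name)``; structures on which the
        selection resolves to nothing are dropped with a warning.
    """
    if isinstance(selection, str):
        selection = AtomSelection(selection)
    if isinstance(paths, (str, Path)):
        expanded = sorted(_glob.glob(str(paths)))
        if not expanded:
            expanded = [str(paths)]
        paths = expanded
    structures = []  # (source_id, keys list, key->row dict, coords, bfac)
    for path in paths:
        for source_id, array in _read_pdb_models(path):
            atoms = _atom_table(array)
            try:
                idx = selection.resolve(atoms)
            except Exception:
                warnings.warn(
                    f"selection {selection.expression!r} matches no atoms in "
                    f"{source_id}; structure dropped"
                )
                continue
            sub = atoms.iloc[idx]
            keys = list(zip(sub["chain_id"], sub["res_id"], sub["atom_name"]))
            key_to_pos = {}
            for local, key in enumerate(keys):
                key_to_pos.setdefault(key, local)  # first altloc wins
            structures.append(
                (source_id, keys, key_to_pos, array.coord[idx], array.b_factor[idx], sub)
            )
    if not structures:
        raise ValueError("no structures survived loading")

    common = set(structures[0][2])
    for _, _, key_to_pos, _, _, _ in structures[1:]:
        common &= set(key_to_pos)
    if not common:
        raise ValueError(
            "atom schema intersection across structures is empty; "
            "check chains / atom names in the selection"
        )
    # schema order: order of first structure's resolved selection
    first_keys = structures[0][1]
    schema_keys = [k for k in dict.fromkeys(first_keys) if k in common]

    coords = []
    bfactors = []
    source_ids = []
    for source_id, _, key_to_pos, xyz, bfac, _ in structures:
        rows = [key_to_pos[k] for k in schema_keys]
        coords.append(xyz[rows])
        bfactors.append(bfac[rows])
        source_ids.append(source_id)
    first = structures[0]
    first_rows = [first[2][k] for k in schema_keys]
    atoms = first[5].iloc[first_rows].reset_index(drop=True)
    return StructureEnsemble(
        coords=np.asarray(coords),
        atoms=atoms,
        b_factors=np.asarray(bfactors),
        source_ids=source_ids,
    )


def write_structure(
    coords: np.ndarray,
    atoms: pd.DataFrame,
    b_factors: np.ndarray,
    path: str | Path,
) -> Path:
    """Write a single structure to a PDB file (B-factor column preserved)."""
    n = len(atoms)
    array = struc.AtomArray(n)
    array.coord = np.asarray(coords, dtype=np.float32)
    array.chain_id = atoms["chain_id"].to_numpy(dtype="U4")
    array.res_id = atoms["res_id"].to_numpy(dtype=int)
    array.res_name = atoms["res_name"].to_numpy(dtype="U5")
    array.atom_name = atoms["atom_name"].to_numpy(dtype="U6")
    array.element = np.array(
        [name.strip()[:1] for name in atoms["atom_name"]], dtype="U2"
    )
    array.set_annotation("b_factor", np.asarray(b_factors, dtype=float))
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(array)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pdb_file.write(str(path))
    return path


def write_ensemble(ensemble: StructureEnsemble, out_dir: str | Path) -> list[Path]:
    """Write each structure of an ensemble as a PDB file named by source id."""
    out_dir = Path(out_dir)
    paths = []
    for i in range(ensemble.n_structures):
        name = ensemble.source_ids[i].replace("#", "_").replace("/", "_")
        if not name.endswith(".pdb"):
            name += ".pdb"
        paths.append(
            write_structure(
                ensemble.coords[i], ensemble.atoms, ensemble.b_factors[i],
                out_dir / name,
            )
        )
    return paths


# ---------------------------------------------------------------------------
# Superposition / RMSD
# ---------------------------------------------------------------------------

def _check_fit_set(points: np.ndarray) -> None:
    if points.shape[0] < 3:
        raise ValueError("superposition requires at least 3 fit atoms")
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) fit atom set")


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_selection=None,
    rmsd_selection=None,
) -> tuple[np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch, proper rotation only).

    Returns the transformed mobile coordinates (all atoms) and the RMSD over
    ``rmsd_selection`` (defaults to ``fit_selection``, which defaults to all
    atoms).  Reflections are excluded, so enantiomers do not superpose to
    zero RMSD.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have identical shapes")
    if fit_selection is None:
        fit_selection = np.arange(mobile.shape[0])
    fit_selection = np.asarray(fit_selection, dtype=int)
    if rmsd_selection is None:
        rmsd_selection = fit_selection
    rmsd_selection = np.asarray(rmsd_selection, dtype=int)

    mob_fit = mobile[fit_selection]
    ref_fit = reference[fit_selection]
    _check_fit_set(mob_fit)
    _check_fit_set(ref_fit)

    mob_centroid = mob_fit.mean(axis=0)
    ref_centroid = ref_fit.mean(axis=0)
    rotation, _ = Rotation.align_vectors(
        ref_fit - ref_centroid, mob_fit - mob_centroid
    )
    transformed = rotation.apply(mobile - mob_centroid) + ref_centroid
    diff = transformed[rmsd_selection] - reference[rmsd_selection]
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return transformed, rmsd


# ---------------------------------------------------------------------------
# Time-series I/O
# ---------------------------------------------------------------------------

def _read_table(path: Path) -> tuple[np.ndarray, list[str] | None]:
    header = None
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if header is None:
                    header = line.lstrip("#").replace(",", " ").split()
                continue
            parts = line.replace(",", " ").split()
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric entry in time series"
                ) from exc
    if not rows:
        raise ValueError(f"{path}: empty time-series file")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ValueError(f"{path}: inconsistent column counts {sorted(widths)}")
    data = np.asarray(rows, dtype=float)
    if header is not None and len(header) != data.shape[1]:
        header = None  # header line was a comment, not column names
    return data, header


def load_timeseries(files, dt: float = 1.0, column_names=None) -> TimeSeries:
    """Load one trajectory per file; trajectories are never concatenated."""
    if isinstance(files, (str, Path)):
        files = [files]
    trajectories = []
    traj_ids = []
    names = list(column_names) if column_names is not None else None
    for path in files:
        path = Path(path)
        data, header = _read_table(path)
        if data.shape[0] < 2:
            raise ValueError(f"{path}: trajectory has fewer than 2 frames")
        if names is None:
            names = header
        if trajectories and data.shape[1] != trajectories[0].shape[1]:
            raise ValueError(
                f"{path}: column count {data.shape[1]} does not match "
                f"{trajectories[0].shape[1]} from earlier files"
            )
        trajectories.append(data)
        traj_ids.append(path.stem)
    return TimeSeries(
        trajectories=trajectories,
        dt=dt,
        column_names=names or [],
        traj_ids=traj_ids,
    )


def write_timeseries(ts: TimeSeries, out_dir: str | Path, fmt: str = "%.10g") -> list[Path]:
    """Write one whitespace-delimited file per trajectory with a '#' header."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    header = " ".join(ts.column_names)
    for traj_id, data in zip(ts.traj_ids, ts.trajectories):
        path = out_dir / f"{traj_id}.dat"
        np.savetxt(path, data, fmt=fmt, header=header)
        paths.append(path)
    return paths
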