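"""Synthetic fixtures: Langevin dynamics in analytic potentials, and
multi-state bead-chain structural ensembles with known labels.

Every downstream stage (feature selection, clustering, AMINO, SPIB) can be
exercised against these fixtures because the ground truth — well membership,
state membership, per-state pLDDT — is known by construction.  The dynamics
are overdamped (Brownian) with kT and friction absorbed into the units:
positions evolve as ``x += -grad V(x) dt + sqrt(2 T dt) xi``.  No claim of
physical realism is made.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit

from .structure_io import TimeSeries, write_structure

__all__ = [
    "HarmonicWell",
    "DoubleWell1D",
    "TripleWell2D",
    "langevin_trajectory",
    "SyntheticEnsembleSpec",
    "make_ensemble",
    "emulate_md_from_centers",
]


# ---------------------------------------------------------------------------
# Potentials
# ---------------------------------------------------------------------------

@dataclass
class HarmonicWell:
    """V(x) = 0.5 * kappa * |x - center|^2 (any dimension)."""

    kappa: float = 1.0
    center: np.ndarray = field(default_factory=lambda: np.zeros(1))
    form = "harmonic"

    def __post_init__(self):
        self.center = np.atleast_1d(np.asarray(self.center, dtype=float))

    @property
    def ndim(self) -> int:
        return self.center.size

    @property
    def minima(self) -> np.ndarray:
        return self.center[None, :]

    def energy(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        return 0.5 * self.kappa * np.sum((x - self.center) ** 2, axis=1)

    def grad(self, x: np.ndarray) -> np.ndarray:
        return self.kappa * (np.atleast_2d(x) - self.center)


@dataclass
class DoubleWell1D:
    """V(x) = barrier * (x^2 - 1)^2: minima at x = ±1, barrier height at x=0
    equal to ``barrier`` (in units of kT when the simulation temperature is 1).
    """

    barrier: float = 8.0
    form = "double_well_1d"

    @property
    def ndim(self) -> int:
        return 1

    @property
    def minima(self) -> np.ndarray:
        return np.array([[-1.0], [1.0]])

    def energy(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)[:, 0]
        return self.barrier * (x * x - 1.0) ** 2

    def grad(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        return 4.0 * self.barrier * x * (x * x - 1.0)


@dataclass
class TripleWell2D:
    """Three metastable wells in 2D with a built-in timescale separation.

    The potential is the negative log of a Gaussian mixture,
    ``V(r) = -ln sum_i w_i exp(-|r - mu_i|^2 / (2 sigma^2))``, so the
    stationary density at temperature 1 is exactly that mixture and barrier
    heights are controlled by the well separations: for two equal-weight wells
    a distance d apart the barrier is approximately ``d^2/(8 sigma^2) - ln 2``
    kT.  Defaults place a *fast* pair (A, B ~3 kT apart) and a *slow* well
    (C, ~7 kT away), so the lag-time dependence of state merging is testable
    by construction.
    """

    centers: np.ndarray = field(
        default_factory=lambda: np.array([[0.0, 0.0], [2.7, 0.0], [1.35, 3.6]])
    )
    weights: np.ndarray = field(default_factory=lambda: np.array([0.4, 0.4, 0.2]))
    sigma: float = 0.5
    form = "triple_well_2d"

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.weights = self.weights / self.weights.sum()

    @property
    def ndim(self) -> int:
        return 2

    @property
    def minima(self) -> np.ndarray:
        return self.centers

    def _log_kernel(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        d2 = np.sum((x[:, None, :] - self.centers[None, :, :]) ** 2, axis=2)
        return np.log(self.weights)[None, :] - d2 / (2.0 * self.sigma**2)

    def energy(self, x: np.ndarray) -> np.ndarray:
        from scipy.special import logsumexp

        return -logsumexp(self._log_kernel(x), axis=1)

    def grad(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x)
        lk = self._log_kernel(x)
        lk -= lk.max(axis=1, keepdims=True)
        resp = np.exp(lk)
        resp /= resp.sum(axis=1, keepdims=True)
        diff = x[:, None, :] - self.centers[None, :, :]
        return np.sum(resp[:, :, None] * diff, axis=1) / self.sigma**2


# ---------------------------------------------------------------------------
# Integrators (numba kernels; noise passed in for seeded reproducibility)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _run_harmonic(x0, noise, dt, kappa, center, stride, bound):
    n_steps = noise.shape[0]
    ndim = x0.size
    n_out = n_steps // stride
    out = np.empty((n_out, ndim))
    x = x0.copy()
    k = 0
    for step in range(n_steps):
        for j in range(ndim):
            x[j] += -kappa * (x[j] - center[j]) * dt + noise[step, j]
            if np.abs(x[j]) > bound:
                return out[:k], False
        if (step + 1) % stride == 0:
            out[k] = x
            k += 1
    return out[:k], True


@njit(cache=True)
def _run_double_well(x0, noise, dt, barrier, stride, bound):
    n_steps = noise.shape[0]
    n_out = n_steps // stride
    out = np.empty((n_out, 1))
    x = x0[0]
    k = 0
    for step in range(n_steps):
        x += -4.0 * barrier * x * (x * x - 1.0) * dt + noise[step, 0]
        if np.abs(x) > bound:
            return out[:k], False
        if (step + 1) % stride == 0:
            out[k, 0] = x
            k += 1
    return out[:k], True


@njit(cache=True)
def _run_gaussian_mixture(x0, noise, dt, centers, logw, sigma2, stride, bound):
    n_steps = noise.shape[0]
    ndim = x0.size
    n_wells = centers.shape[0]
    n_out = n_steps // stride
    out = np.empty((n_out, ndim))
    x = x0.copy()
    k = 0
    lk = np.empty(n_wells)
    for step in range(n_steps):
        # responsibilities of the mixture components at x
        m = -1e300
        for i in range(n_wells):
            d2 = 0.0
            for j in range(ndim):
                d = x[j] - centers[i, j]
                d2 += d * d
            lk[i] = logw[i] - d2 / (2.0 * sigma2)
            if lk[i] > m:
                m = lk[i]
        tot = 0.0
        for i in range(n_wells):
            lk[i] = np.exp(lk[i] - m)
            tot += lk[i]
        for j in range(ndim):
            g = 0.0
            for i in range(n_wells):
                g += (lk[i] / tot) * (x[j] - centers[i, j])
            x[j] += -(g / sigma2) * dt + noise[step, j]
            if np.abs(x[j]) > bound:
                return out[:k], False
        if (step + 1) % stride == 0:
            out[k] = x
            k += 1
    return out[:k], True


def assign_wells(positions: np.ndarray, minima: np.ndarray) -> np.ndarray:
    """Ground-truth labels: index of the nearest potential minimum."""
    positions = np.atleast_2d(positions)
    d2 = np.sum((positions[:, None, :] - minima[None, :, :]) ** 2, axis=2)
    return np.argmin(d2, axis=1)


def langevin_trajectory(
    potential,
    n_steps: int,
    step_size: float,
    temperature: float = 1.0,
    seed: int = 0,
    x0=None,
    stride: int = 1,
    domain_bound: float = 50.0,
) -> tuple[TimeSeries, np.ndarray]:
    """Overdamped Langevin (Euler-Maruyama) sampling of an analytic potential.

    Returns a :class:`TimeSeries` with one trajectory of the strided
    positions (columns ``x0, x1, ...``) and the per-frame ground-truth well
    label (nearest potential minimum).

    Raises ``RuntimeError`` if the trajectory leaves ``|x| > domain_bound``,
    which indicates an unstable step size.
    """
    rng = np.random.default_rng(seed)
    ndim = potential.ndim
    if x0 is None:
        x0 = potential.minima[0]
    x0 = np.atleast_1d(np.asarray(x0, dtype=float)).copy()
    amp = np.sqrt(2.0 * temperature * step_size)
    noise = amp * rng.standard_normal((n_steps, ndim))

    if potential.form == "harmonic":
        out, ok = _run_harmonic(
            x0, noise, step_size, potential.kappa, potential.center,
            stride, domain_bound,
        )
    elif potential.form == "double_well_1d":
        out, ok = _run_double_well(
            x0, noise, step_size, potential.barrier, stride, domain_bound
        )
    elif potential.form == "triple_well_2d":
        out, ok = _run_gaussian_mixture(
            x0, noise, step_size, potential.centers,
            np.log(potential.weights), potential.sigma**2,
            stride, domain_bound,
        )
    else:  # pragma: no cover - guarded by the dataclasses above
        raise ValueError(f"unknown potential form {potential.form!r}")
    if not ok:
        raise RuntimeError(
            "trajectory diverged (position left the domain bound); "
            "use a smaller step_size"
        )
    labels = assign_wells(out, potential.minima)
    ts = TimeSeries(
        trajectories=[out],
        dt=step_size * stride,
        column_names=[f"x{i}" for i in range(ndim)],
        traj_ids=[f"{potential.form}_seed{seed}"],
    )
    return ts, labels


# ---------------------------------------------------------------------------
# Synthetic structural ensembles
# ---------------------------------------------------------------------------

@dataclass
class SyntheticEnsembleSpec:
    """Bead-chain ensemble with hinge-displaced states.

    A linear C-alpha chain of ``n_beads`` beads (3.8 A spacing) is bent at
    its midpoint by a per-state hinge angle; each structure adds isotropic
    Gaussian coordinate noise of width ``noise_sigma`` (A).  B-factors carry
    a per-state pLDDT value, emulating AlphaFold2 confidence differences
    between conformational states.
    """

    n_states: int = 2
    structures_per_state: int = 50
    n_beads: int = 20
    hinge_angles: list[float] = field(default_factory=lambda: [0.0, 30.0])
    noise_sigma: float = 0.3
    plddt_by_state: list[float] = field(default_factory=lambda: [90.0, 80.0])
    seed: int = 0

    def __post_init__(self):
        if len(self.hinge_angles) != self.n_states:
            raise ValueError("hinge_angles must list one angle per state")
        if len(self.plddt_by_state) != self.n_states:
            raise ValueError("plddt_by_state must list one value per state")


BOND_LENGTH = 3.8  # Calpha-Calpha distance, Angstrom


def _chain_coords(n_beads: int, hinge_angle_deg: float) -> np.ndarray:
    """Straight chain along +x, second half bent by the hinge angle in xy."""
    coords = np.zeros((n_beads, 3))
    mid = n_beads // 2
    coords[: mid + 1, 0] = np.arange(mid + 1) * BOND_LENGTH
    theta = np.deg2rad(hinge_angle_deg)
    direction = np.array([np.cos(theta), np.sin(theta), 0.0])
    for i in range(mid + 1, n_beads):
        coords[i] = coords[i - 1] + BOND_LENGTH * direction
    return coords


def make_ensemble(
    spec: SyntheticEnsembleSpec, out_dir: str | Path
) -> tuple[list[Path], pd.DataFrame]:
    """Write bead-chain PDB files and return (paths, ground-truth table).

    The truth table maps each written file to its state index and pLDDT.
    """
    rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    templates = [_chain_coords(spec.n_beads, a) for a in spec.hinge_angles]
    # inter-state displacement scale: max per-bead displacement between states
    if spec.n_states > 1:
        disp = min(
            np.abs(templates[i] - templates[j]).max()
            for i in range(spec.n_states)
            for j in range(i + 1, spec.n_states)
        )
        if spec.noise_sigma >= disp / 4.0:
            warnings.warn(
                f"noise sigma {spec.noise_sigma} is large relative to the "
                f"inter-state displacement {disp:.2f}; states may overlap"
            )

    atoms = pd.DataFrame(
        {
            "chain_id": ["A"] * spec.n_beads,
            "res_id": np.arange(1, spec.n_beads + 1),
            "res_name": ["ALA"] * spec.n_beads,
            "atom_name": ["CA"] * spec.n_beads,
        }
    )
    paths = []
    records = []
    for state in range(spec.n_states):
        for rep in range(spec.structures_per_state):
            coords = templates[state] + spec.noise_sigma * rng.standard_normal(
                (spec.n_beads, 3)
            )
            bfac = np.full(spec.n_beads, spec.plddt_by_state[state])
            name = f"state{state}_rep{rep:03d}.pdb"
            path = write_structure(coords, atoms, bfac, out_dir / name)
            paths.append(path)
            records.append(
                {"file": name, "state": state, "plddt": spec.plddt_by_state[state]}
            )
    truth = pd.DataFrame(records)
    return paths, truth


# ---------------------------------------------------------------------------
# Redundant-CV fixture for mutual-information pruning
# ---------------------------------------------------------------------------

def redundant_cv_series(
    n_groups: int = 3,
    copies_per_group: int = 5,
    n_frames: int = 5000,
    noise: float = 0.1,
    ar_coefficient: float = 0.95,
    seed: int = 0,
) -> tuple[TimeSeries, np.ndarray]:
    """Independent AR(1) signals, each observed as several noisy copies.

    Emulates the redundancy of variance-ranked distance CVs: the distance
    between residues (m, n) and the one between (m±1, n±1) track the same
    underlying motion and differ only by small independent noise — hence the
    default relative noise of 0.1, giving copies that share most of their
    information.  Returns the series (columns named ``g<group>c<copy>``) and
    the ground-truth group index per column.
    """
    rng = np.random.default_rng(seed)
    a = ar_coefficient
    base = np.empty((n_frames, n_groups))
    eps = rng.standard_normal((n_frames, n_groups))
    base[0] = eps[0]
    for t in range(1, n_frames):
        base[t] = a * base[t - 1] + np.sqrt(1 - a * a) * eps[t]
    columns, names, groups = [], [], []
    for g in range(n_groups):
        for c in range(copies_per_group):
            columns.append(base[:, g] + noise * rng.standard_normal(n_frames))
            names.append(f"g{g}c{c}")
            groups.append(g)
    ts = TimeSeries(
        trajectories=[np.stack(columns, axis=1)], column_names=names
    )
    return ts, np.asarray(groups)


# ---------------------------------------------------------------------------
# Toy stand-in for the short-MD stage of the pipeline
# ---------------------------------------------------------------------------

def emulate_md_from_centers(
    center_features: np.ndarray,
    column_names: list[str],
    n_frames: int = 5000,
    kappa: float = 1.0,
    temperature: float = 0.05,
    dt: float = 0.1,
    seed: int = 0,
) -> TimeSeries:
    """Emulate short MD runs launched from each cluster center.

    Each trajectory is overdamped Langevin diffusion of the feature vector in
    an isotropic harmonic basin centred on one cluster center — a stand-in
    for local conformational sampling around a seed structure.  Fluctuation
    scale is ``sqrt(temperature / kappa)`` per feature (exact OU update, so
    any ``dt`` is stable).
    """
    center_features = np.atleast_2d(np.asarray(center_features, dtype=float))
    rng = np.random.default_rng(seed)
    a = np.exp(-kappa * dt)
    sd = np.sqrt(temperature / kappa * (1.0 - a * a))
    trajectories = []
    for c in center_features:
        x = np.empty((n_frames, c.size))
        noise = rng.standard_normal((n_frames, c.size))
        prev = np.zeros(c.size)
        for t in range(n_frames):
            prev = prev * a + sd * noise[t]
            x[t] = c + prev
        trajectories.append(x)
    return TimeSeries(
        trajectories=trajectories,
        dt=dt,
        column_names=list(column_names),
        traj_ids=[f"center{i}" for i in range(len(trajectories))],
    )
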