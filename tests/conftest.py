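import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from statefinder import toy_dynamics as td


def matched_accuracy(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Label-agreement after optimal one-to-one state/well matching."""
    states = np.unique(predicted)
    wells = np.unique(truth)
    overlap = np.zeros((len(states), len(wells)))
    for i, s in enumerate(states):
        for j, w in enumerate(wells):
            overlap[i, j] = np.sum((predicted == s) & (truth == w))
    rows, cols = linear_sum_assignment(-overlap)
    return overlap[rows, cols].sum() / len(predicted)


@pytest.fixture(scope="session")
def two_state_ensemble(tmp_path_factory):
    """Synthetic 2-state hinge ensemble on disk plus its ground truth."""
    out = tmp_path_factory.mktemp("ensemble")
    spec = td.SyntheticEnsembleSpec(
        n_states=2,
        structures_per_state=50,
        n_beads=20,
        hinge_angles=[0.0, 30.0],
        noise_sigma=0.3,
        plddt_by_state=[90.0, 80.0],
        seed=7,
    )
    paths, truth = td.make_ensemble(spec, out)
    return out, paths, truth, spec


@pytest.fixture(scope="session")
def double_well_series():
    """1D double-well Langevin trajectory (barrier 8 kT) with well labels."""
    return td.langevin_trajectory(
        td.DoubleWell1D(barrier=8.0),
        n_steps=1_000_000,
        step_size=0.002,
        temperature=1.0,
        seed=2,
        stride=10,
    )


@pytest.fixture(scope="session")
def triple_well_series():
    """2D triple-well trajectory: fast A-B pair, slow well C."""
    return td.langevin_trajectory(
        td.TripleWell2D(),
        n_steps=1_000_000,
        step_size=0.01,
        temperature=1.0,
        seed=3,
        stride=20,
    )
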