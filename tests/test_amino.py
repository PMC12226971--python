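import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from statefinder import toy_dynamics as td
from statefinder.amino import (
    amino_reduce,
    discretize,
    joint_entropy,
    mi_distance,
    mutual_information,
)
from statefinder.structure_io import TimeSeries


def _ts(columns: dict[str, np.ndarray]) -> TimeSeries:
    names = list(columns)
    return TimeSeries(
        trajectories=[np.stack([columns[n] for n in names], axis=1)],
        column_names=names,
    )


def labels_from_joint(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expand a joint count table into paired label arrays."""
    xs, ys = [], []
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            xs += [i] * counts[i, j]
            ys += [j] * counts[i, j]
    return np.array(xs), np.array(ys)


def plugin_mi_oracle(counts: np.ndarray) -> float:
    """Direct scalar-sum evaluation of the plug-in MI formula (bits)."""
    p = counts / counts.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    total = 0.0
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            if p[i, j] > 0:
                total += p[i, j] * np.log2(p[i, j] / (px[i] * py[j]))
    return total


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

def test_two_bins_split():
    ts = _ts({"a": np.array([0.0, 1.0, 2.0, 3.0])})
    disc = discretize(ts, n_bins=2)
    assert disc.labels[:, 0].tolist() == [0, 0, 1, 1]


def test_constant_column_warns_all_zero():
    ts = _ts({"a": np.full(10, 3.0)})
    with pytest.warns(UserWarning, match="constant"):
        disc = discretize(ts, n_bins=4)
    assert np.all(disc.labels == 0)


def test_uniform_draws_fill_bins_evenly():
    rng = np.random.default_rng(0)
    ts = _ts({"a": rng.uniform(size=10_000)})
    disc = discretize(ts, n_bins=10)
    freq = np.bincount(disc.labels[:, 0], minlength=10) / 10_000
    assert np.all(np.abs(freq - 0.1) < 0.02)


def test_maximum_lands_in_last_bin():
    ts = _ts({"a": np.linspace(0, 1, 11)})
    disc = discretize(ts, n_bins=5)
    assert disc.labels[-1, 0] == 4


# ---------------------------------------------------------------------------
# information measures
# ---------------------------------------------------------------------------

def test_identical_fair_binary_gives_one_bit():
    x = np.array([0, 1] * 500)
    assert mutual_information(x, x) == pytest.approx(1.0, abs=1e-12)


def test_exact_product_table_gives_zero():
    x, y = labels_from_joint(np.array([[25, 25], [25, 25]]))
    assert mutual_information(x, y) == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize(
    "counts",
    [
        np.array([[40, 10], [10, 40]]),
        np.array([[5, 0, 3], [2, 7, 1], [0, 4, 8]]),
        np.array([[99, 1], [1, 99]]),
    ],
)
def test_mi_matches_direct_sum_oracle(counts):
    x, y = labels_from_joint(counts)
    assert mutual_information(x, y) == pytest.approx(
        plugin_mi_oracle(counts), abs=1e-12
    )


def test_length_mismatch_raises():
    with pytest.raises(ValueError, match="equal length"):
        mutual_information(np.zeros(3), np.zeros(4))


def test_distance_zero_for_identical_nonconstant():
    x = np.array([0, 1, 2, 0, 1, 2])
    assert mi_distance(x, x) == 0.0


def test_distance_one_for_independent_fair_binary():
    x, y = labels_from_joint(np.array([[25, 25], [25, 25]]))
    assert joint_entropy(x, y) == pytest.approx(2.0, abs=1e-12)
    assert mi_distance(x, y) == pytest.approx(1.0, abs=1e-12)


def test_both_constant_defined_as_zero_with_warning():
    x = np.zeros(10, dtype=int)
    with pytest.warns(UserWarning, match="constant"):
        assert mi_distance(x, x) == 0.0


def test_distance_increases_with_noise():
    rng = np.random.default_rng(4)
    x = rng.normal(size=20_000)
    dists = []
    for noise in (0.1, 0.5, 2.0):
        y = x + noise * rng.normal(size=x.size)
        ts = _ts({"x": x, "y": y})
        disc = discretize(ts, n_bins=20)
        dists.append(mi_distance(disc.labels[:, 0], disc.labels[:, 1]))
    assert 0 < dists[0] < dists[1] < dists[2] < 1


@settings(max_examples=60, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n=st.integers(10, 400), bins=st.integers(2, 8))
def test_distance_is_bounded_symmetric_dissimilarity(seed, n, bins):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, bins, size=n)
    y = rng.integers(0, bins, size=n)
    d_xy = mi_distance(x, y)
    assert 0.0 <= d_xy <= 1.0
    assert d_xy == pytest.approx(mi_distance(y, x), abs=1e-12)
    assert mi_distance(x, x) == 0.0


# ---------------------------------------------------------------------------
# AMINO reduction
# ---------------------------------------------------------------------------

def test_duplicated_groups_recovers_three_medoids():
    ts, groups = td.redundant_cv_series(n_groups=3, copies_per_group=5, seed=0)
    result = amino_reduce(ts, k_max=8, seed=0)
    assert result.k == 3
    medoid_groups = sorted(groups[m] for m in result.medoid_indices)
    assert medoid_groups == [0, 1, 2]
    # every CV is assigned to the medoid from its own group
    for i in range(ts.n_cvs):
        assert groups[result.medoid_indices[result.assignments[i]]] == groups[i]


def test_exact_copies_collapse_to_one():
    x = np.random.default_rng(1).normal(size=1000)
    ts = _ts({"a": x, "b": x.copy()})
    result = amino_reduce(ts, k_max=2, seed=0)
    assert result.k == 1


def test_independent_signals_all_kept():
    rng = np.random.default_rng(2)
    ts = TimeSeries(
        trajectories=[rng.normal(size=(5000, 10))],
        column_names=[f"i{j}" for j in range(10)],
    )
    result = amino_reduce(ts, k_max=10, seed=0)
    assert result.k == 10


def test_column_permutation_recovers_same_groups():
    ts, groups = td.redundant_cv_series(seed=3)
    perm = np.random.default_rng(9).permutation(ts.n_cvs)
    permuted = TimeSeries(
        trajectories=[ts.trajectories[0][:, perm]],
        column_names=[ts.column_names[i] for i in perm],
    )
    r1 = amino_reduce(ts, k_max=8, seed=0)
    r2 = amino_reduce(permuted, k_max=8, seed=0)
    assert r1.k == r2.k == 3
    groups1 = {frozenset(np.flatnonzero(r1.assignments == c)) for c in range(3)}
    names2 = [permuted.column_names[i] for i in range(15)]
    # map permuted assignment clusters back to original column indices
    groups2 = set()
    for c in range(3):
        members = [ts.column_names.index(names2[i]) for i in np.flatnonzero(r2.assignments == c)]
        groups2.add(frozenset(members))
    assert groups1 == groups2


def test_adding_duplicate_never_increases_k():
    ts, _ = td.redundant_cv_series(seed=5)
    base = amino_reduce(ts, k_max=8, seed=0)
    dup = TimeSeries(
        trajectories=[
            np.concatenate([ts.trajectories[0], ts.trajectories[0][:, :1]], axis=1)
        ],
        column_names=ts.column_names + ["dup_of_g0c0"],
    )
    extended = amino_reduce(dup, k_max=8, seed=0)
    assert extended.k <= base.k


def test_group_recovery_across_ten_seeds():
    hits = 0
    for seed in range(10):
        ts, groups = td.redundant_cv_series(seed=seed)
        result = amino_reduce(ts, k_max=8, seed=seed)
        ok = result.k == 3 and all(
            groups[result.medoid_indices[result.assignments[i]]] == groups[i]
            for i in range(ts.n_cvs)
        )
        hits += ok
    assert hits == 10


def test_k_max_clamped_with_warning():
    x = np.random.default_rng(6).normal(size=(500, 3))
    ts = TimeSeries(trajectories=[x], column_names=["a", "b", "c"])
    with pytest.warns(UserWarning, match="clamping"):
        result = amino_reduce(ts, k_max=10, seed=0)
    assert result.k <= 3


def test_distance_matrix_is_symmetric_zero_diagonal():
    ts, _ = td.redundant_cv_series(seed=7, n_frames=2000)
    result = amino_reduce(ts, k_max=8, seed=0)
    D = result.distance_matrix
    assert np.allclose(D, D.T)
    assert np.all(np.diag(D) == 0)
    assert set(result.selected) <= set(ts.column_names)
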