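import numpy as np
import pytest

from conftest import matched_accuracy
from statefinder.spib import (
    SPIB,
    SpibConfig,
    SpibResult,
    _encode,
    _log_softmax,
    _prior_log_pdf,
    _SpibNet,
    init_labels,
    lagged_pairs,
    train_spib,
)
from statefinder.structure_io import TimeSeries


def _blob_series(seed=0, n=400, separation=6.0, n_cols=2, two_trajs=False):
    """Two well-separated OU blobs as one (or two) trajectories."""
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(n, n_cols)) * 0.5
    b = rng.normal(size=(n, n_cols)) * 0.5 + separation
    truth = np.concatenate([np.zeros(n, dtype=int), np.ones(n, dtype=int)])
    if two_trajs:
        return TimeSeries(trajectories=[a, b]), truth
    return TimeSeries(trajectories=[np.vstack([a, b])]), truth


# ---------------------------------------------------------------------------
# initial labels
# ---------------------------------------------------------------------------

def test_init_labels_separate_blobs():
    ts, truth = _blob_series()
    labels = init_labels(ts, 2, seed=0)
    assert matched_accuracy(labels.pooled(), truth) >= 0.99


def test_single_state_allowed():
    ts, _ = _blob_series()
    labels = init_labels(ts, 1, seed=0)
    assert np.all(labels.pooled() == 0)


def test_identical_frames_collapse_warns():
    ts = TimeSeries(trajectories=[np.ones((50, 2))])
    with pytest.warns(UserWarning, match="distinct clusters"):
        init_labels(ts, 2, seed=0)


def test_more_states_than_frames_rejected():
    ts = TimeSeries(trajectories=[np.zeros((5, 1))])
    with pytest.raises(ValueError, match="exceeds"):
        init_labels(ts, 10, seed=0)


# ---------------------------------------------------------------------------
# prediction pairs
# ---------------------------------------------------------------------------

def test_no_pair_spans_trajectory_boundary():
    ts = TimeSeries(trajectories=[np.zeros((10, 1)), np.zeros((7, 1))])
    src, tgt = lagged_pairs(ts, lag_steps=3)
    assert len(src) == (10 - 3) + (7 - 3)
    # first trajectory occupies global indices 0..9, second 10..16
    same_traj = (src < 10) == (tgt < 10)
    assert np.all(same_traj)
    assert np.all(tgt - src == 3)


def test_lag_must_be_shorter_than_shortest_trajectory():
    ts = TimeSeries(trajectories=[np.zeros((100, 1)), np.zeros((5, 1))])
    with pytest.raises(ValueError, match="shortest trajectory"):
        SPIB(ts, SpibConfig(lag_steps=5))


# ---------------------------------------------------------------------------
# network internals
# ---------------------------------------------------------------------------

def _total_loss(params, X, y, eps, cfg):
    """Loss recomputed from parameters alone (for finite differences)."""
    hs, mu, lv = _encode(params, X, cfg.n_hidden)
    std = np.exp(0.5 * lv)
    z = mu + std * eps
    logits = z @ params["Wd"].T + params["bd"]
    ce = -_log_softmax(logits)[np.arange(len(y)), y]
    logq = -0.5 * np.sum(np.log(2 * np.pi) + lv + ((z - mu) / std) ** 2, axis=1)
    logp, *_ = _prior_log_pdf(params, z)
    return float(np.mean(ce) + cfg.beta * np.mean(logq - logp))


def test_gradients_match_finite_differences():
    cfg = SpibConfig(
        lag_steps=1, latent_dim=2, n_initial_states=3, hidden_dim=5, beta=0.05
    )
    rng = np.random.default_rng(0)
    net = _SpibNet(3, cfg, rng)
    X = rng.normal(size=(6, 3))
    y = rng.integers(0, 3, size=6)
    eps = rng.standard_normal((6, 2))

    # capture analytic gradients by intercepting the optimizer
    grads = {}
    net.opt.step = lambda p, g: grads.update(g)
    net.rng = type("R", (), {"standard_normal": lambda self, shape: eps})()
    net.train_step(X, y)

    h = 1e-6
    for key in ["W0", "bm", "Wv", "Wd", "pm", "plv", "pa"]:
        p = net.params[key]
        flat = p.ravel()
        for idx in [0, flat.size // 2, flat.size - 1]:
            orig = flat[idx]
            flat[idx] = orig + h
            up = _total_loss(net.params, X, y, eps, cfg)
            flat[idx] = orig - h
            down = _total_loss(net.params, X, y, eps, cfg)
            flat[idx] = orig
            numeric = (up - down) / (2 * h)
            assert grads[key].ravel()[idx] == pytest.approx(
                numeric, rel=1e-4, abs=1e-7
            ), key


def test_decoder_outputs_probability_vectors():
    cfg = SpibConfig(lag_steps=1, n_initial_states=4)
    rng = np.random.default_rng(1)
    net = _SpibNet(2, cfg, rng)
    probs = net.decode(rng.normal(size=(100, cfg.latent_dim)))
    assert np.all(probs >= 0)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)


# ---------------------------------------------------------------------------
# training behavior
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def blob_fit():
    ts, truth = _blob_series(n=600)
    cfg = SpibConfig(lag_steps=2, n_initial_states=4, seed=0, max_epochs=60)
    result = SPIB(ts, cfg).fit()
    return ts, truth, cfg, result


def test_two_blobs_give_two_states(blob_fit):
    _, truth, _, result = blob_fit
    assert result.n_states == 2
    assert matched_accuracy(result.labels.pooled(), truth) >= 0.99


def test_training_is_deterministic_given_seed(blob_fit):
    ts, _, cfg, result = blob_fit
    again = SPIB(ts, cfg).fit()
    assert np.array_equal(result.labels.pooled(), again.labels.pooled())
    for k in result.params:
        assert np.array_equal(result.params[k], again.params[k])


def test_projection_self_consistency(blob_fit):
    ts, _, _, result = blob_fit
    _, posterior, states = result.project(ts.pooled())
    assert np.mean(states == result.labels.pooled()) >= 0.99
    assert np.allclose(posterior.sum(axis=1), 1.0, atol=1e-6)


def test_duplicated_frame_projects_identically(blob_fit):
    ts, _, _, result = blob_fit
    frame = ts.pooled()[:1]
    latent, posterior, states = result.project(np.repeat(frame, 3, axis=0))
    assert np.array_equal(latent[0], latent[1]) and np.array_equal(latent[1], latent[2])
    assert states[0] == states[1] == states[2]


def test_file_order_does_not_change_learned_states():
    ts_ab, truth = _blob_series(two_trajs=True)
    ts_ba = TimeSeries(trajectories=list(reversed(ts_ab.trajectories)))
    cfg = SpibConfig(lag_steps=2, n_initial_states=4, seed=0, max_epochs=60)
    res_ab = SPIB(ts_ab, cfg).fit()
    res_ba = SPIB(ts_ba, cfg).fit()
    assert res_ab.n_states == res_ba.n_states == 2
    truth_ba = np.concatenate([np.ones(400, dtype=int), np.zeros(400, dtype=int)])
    assert matched_accuracy(res_ab.labels.pooled(), truth) >= 0.99
    assert matched_accuracy(res_ba.labels.pooled(), truth_ba) >= 0.99


def test_single_blob_collapses_to_one_state_with_warning():
    rng = np.random.default_rng(3)
    ts = TimeSeries(trajectories=[rng.normal(size=(800, 2))])
    cfg = SpibConfig(lag_steps=10, n_initial_states=4, seed=0, max_epochs=60)
    with pytest.warns(UserWarning, match="single state"):
        result = SPIB(ts, cfg).fit()
    assert result.n_states == 1


def test_train_spib_functional_wrapper():
    ts, truth = _blob_series(n=300)
    cfg = SpibConfig(lag_steps=2, n_initial_states=3, seed=1, max_epochs=40)
    result, labels = train_spib(ts, None, cfg)
    assert labels.n_states == result.n_states
    assert len(labels.labels) == len(ts.trajectories)


def test_schema_mismatch_lists_missing_columns(blob_fit):
    _, _, _, result = blob_fit
    with pytest.raises(ValueError, match="missing CV columns"):
        result.project(np.zeros((2, 2)), column_names=["other0", "cv1"])
    with pytest.raises(ValueError, match="does not match"):
        result.project(np.zeros((2, 5)))


def test_save_load_roundtrip(tmp_path, blob_fit):
    ts, _, _, result = blob_fit
    path = result.save(tmp_path / "model.npz")
    loaded = SpibResult.load(path)
    X = ts.pooled()[:20]
    z1, p1, s1 = result.project(X)
    z2, p2, s2 = loaded.project(X)
    assert np.array_equal(s1, s2)
    assert np.allclose(z1, z2)
    assert np.allclose(p1, p2)


def test_summary_mentions_state_count(blob_fit):
    *_, result = blob_fit
    text = result.summary()
    assert "metastable states:  2" in text


def test_scan_identical_lags_give_identical_counts():
    ts, _ = _blob_series(n=300)
    from statefinder.spib import state_count_scan

    cfg = SpibConfig(lag_steps=2, n_initial_states=3, seed=4, max_epochs=40)
    records = state_count_scan(ts, cfg, lags=[2, 2])
    assert records[0]["n_states"] == records[1]["n_states"]
    assert records[0]["seed"] == records[1]["seed"]
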