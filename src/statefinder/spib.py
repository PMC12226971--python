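"""State Predictive Information Bottleneck (SPIB).

SPIB learns a low-dimensional stochastic latent representation z of the CV
vector x_t that retains only the information needed to predict the system's
*state label* a lag time Delta-t into the future.  Training minimizes

    E[ -log p_decoder(y_{t+lag} | z_t) ]  +  beta * KL( q(z|x_t) || p(z) )

where q(z|x) is a Gaussian encoder, p(z) a learnable mixture-of-Gaussians
prior (one component per state), and y the current label set.  Periodically
every frame is relabeled to the argmax decoded state of its own encoded
representation; states that lose all frames die, and the procedure converges
to a set of metastable states whose number depends on the lag: lags longer
than the interconversion time of a pair of states merge them.

The network is a small multilayer perceptron implemented directly in NumPy
(tanh hidden layers, linear Gaussian latent head, linear-softmax decoder)
with analytically derived gradients and an Adam optimizer; training is
deterministic given the seed.  Prediction pairs are formed strictly within
each trajectory, never across trajectory boundaries.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .structure_io import TimeSeries

_LOG2PI = np.log(2.0 * np.pi)
_LV_CLIP = 12.0


# ---------------------------------------------------------------------------
# Configuration and label container
# ---------------------------------------------------------------------------

@dataclass
class SpibConfig:
    """Hyperparameters for SPIB training.

    ``lag_steps`` (the prediction horizon in frames) is the physically
    meaningful knob: it sets the timescale below which dynamics are treated
    as intra-state noise.  Everything else controls the variational model
    and its optimization.
    """

    lag_steps: int
    latent_dim: int = 2
    beta: float = 0.01
    n_initial_states: int = 10
    refinement_interval: int = 3  # epochs between relabeling passes
    convergence_tol: float = 0.01  # max fraction of frames changing label
    patience: int = 10  # consecutive sub-tol refinements required
    max_epochs: int = 150
    seed: int = 0
    hidden_dim: int = 64
    n_hidden: int = 2
    learning_rate: float = 2e-3
    batch_size: int = 1024

    def __post_init__(self):
        if self.lag_steps < 1:
            raise ValueError("lag_steps must be >= 1")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")


@dataclass
class StateLabels:
    """Per-trajectory integer state labels (+ optional 2D latent means)."""

    labels: list[np.ndarray]
    n_states: int
    latent: list[np.ndarray] | None = None

    def pooled(self) -> np.ndarray:
        return np.concatenate(self.labels)


def init_labels(ts: TimeSeries, n_initial_states: int, seed: int = 0) -> StateLabels:
    """Initial discrete labels from seeded k-means on the pooled frames.

    The initial count should overshoot the expected number of metastable
    states; SPIB's refinement prunes downward, never upward.
    """
    if n_initial_states < 1:
        raise ValueError("n_initial_states must be >= 1")
    X = ts.pooled()
    if n_initial_states > X.shape[0]:
        raise ValueError("n_initial_states exceeds the number of frames")
    if n_initial_states == 1:
        pooled = np.zeros(X.shape[0], dtype=int)
    else:
        km = KMeans(n_clusters=n_initial_states, n_init=5, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sklearn warns on duplicate points
            pooled = km.fit_predict(X)
        found = len(np.unique(pooled))
        if found < n_initial_states:
            warnings.warn(
                f"k-means produced only {found} distinct clusters "
                f"(requested {n_initial_states}); degenerate input"
            )
    out = []
    offset = 0
    for t in ts.trajectories:
        out.append(pooled[offset : offset + t.shape[0]].astype(int))
        offset += t.shape[0]
    return StateLabels(labels=out, n_states=int(pooled.max()) + 1)


def lagged_pairs(ts: TimeSeries, lag_steps: int) -> tuple[np.ndarray, np.ndarray]:
    """Global (source, target) frame indices of all time-lagged prediction
    pairs, formed strictly within each trajectory (indices refer to the
    pooled, trajectory-major frame order)."""
    src, tgt = [], []
    offset = 0
    for t in ts.trajectories:
        n = t.shape[0]
        idx = np.arange(n - lag_steps)
        src.append(offset + idx)
        tgt.append(offset + idx + lag_steps)
        offset += n
    return np.concatenate(src), np.concatenate(tgt)


# ---------------------------------------------------------------------------
# The network
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: dict, lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )


def _init_params(
    n_in: int, cfg: SpibConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    p: dict[str, np.ndarray] = {}
    dims = [n_in] + [cfg.hidden_dim] * cfg.n_hidden
    for i in range(cfg.n_hidden):
        p[f"W{i}"] = rng.standard_normal((dims[i + 1], dims[i])) / np.sqrt(dims[i])
        p[f"b{i}"] = np.zeros(dims[i + 1])
    h = dims[-1]
    L, S = cfg.latent_dim, cfg.n_initial_states
    p["Wm"] = rng.standard_normal((L, h)) / np.sqrt(h)
    p["bm"] = np.zeros(L)
    p["Wv"] = rng.standard_normal((L, h)) / np.sqrt(h)
    p["bv"] = np.full(L, -2.0)  # start with small encoder variance
    p["Wd"] = rng.standard_normal((S, L)) / np.sqrt(L)
    p["bd"] = np.zeros(S)
    p["pm"] = 0.1 * rng.standard_normal((S, L))
    p["plv"] = np.zeros((S, L))
    p["pa"] = np.zeros(S)
    return p


def _encode(p: dict, X: np.ndarray, n_hidden: int):
    hs = [X]
    h = X
    for i in range(n_hidden):
        h = np.tanh(h @ p[f"W{i}"].T + p[f"b{i}"])
        hs.append(h)
    mu = h @ p["Wm"].T + p["bm"]
    lv = np.clip(h @ p["Wv"].T + p["bv"], -_LV_CLIP, _LV_CLIP)
    return hs, mu, lv

def _log_softmax(logits: np.ndarray) -> np.ndarray:
    return logits - logsumexp(logits, axis=1, keepdims=True)


def _prior_log_pdf(p: dict, z: np.ndarray):
    """Mixture-prior log density and responsibilities at z."""
    logw = p["pa"] - logsumexp(p["pa"])
    pvar = np.exp(p["plv"])
    # (B, S): component log joint
    diff = z[:, None, :] - p["pm"][None, :, :]
    lc = logw[None, :] - 0.5 * np.sum(
        _LOG2PI + p["plv"][None, :, :] + diff * diff / pvar[None, :, :], axis=2
    )
    logp = logsumexp(lc, axis=1)
    resp = np.exp(lc - logp[:, None])
    return logp, resp, diff, pvar, logw


class _SpibNet:
    """Forward/backward passes and refinement machinery."""

    def __init__(self, n_in: int, cfg: SpibConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.params = _init_params(n_in, cfg, rng)
        self.opt = _Adam(self.params, cfg.learning_rate)

    # -- inference ---------------------------------------------------------
    def encode_mean(self, X: np.ndarray) -> np.ndarray:
        _, mu, _ = _encode(self.params, X, self.cfg.n_hidden)
        return mu

    def decode(self, z: np.ndarray) -> np.ndarray:
        logits = z @ self.params["Wd"].T + self.params["bd"]
        return np.exp(_log_softmax(logits))

    def predict_states(self, X: np.ndarray, chunk: int = 65536) -> np.ndarray:
        out = np.empty(X.shape[0], dtype=int)
        for s in range(0, X.shape[0], chunk):
            mu = self.encode_mean(X[s : s + chunk])
            logits = mu @ self.params["Wd"].T + self.params["bd"]
            out[s : s + chunk] = np.argmax(logits, axis=1)
        return out

    # -- training ----------------------------------------------------------
    def train_step(self, X: np.ndarray, y: np.ndarray) -> float:
        p = self.params
        cfg = self.cfg
        B = X.shape[0]
        hs, mu, lv = _encode(p, X, cfg.n_hidden)
        h = hs[-1]
        std = np.exp(0.5 * lv)
        eps = self.rng.standard_normal(mu.shape)
        z = mu + std * eps
        var = std * std
        zmu = z - mu

        logits = z @ p["Wd"].T + p["bd"]
        logq_y = _log_softmax(logits)
        ce = -logq_y[np.arange(B), y]
        P = np.exp(logq_y)

        logq_z = -0.5 * np.sum(_LOG2PI + lv + eps * eps, axis=1)
        logp_z, resp, pdiff, pvar, logw = _prior_log_pdf(p, z)
        kl = logq_z - logp_z
        loss = float(np.mean(ce) + cfg.beta * np.mean(kl))
        if not np.isfinite(loss):
            raise RuntimeError(
                "non-finite SPIB loss "
                f"(mean CE {np.mean(ce):.3g}, mean KL {np.mean(kl):.3g}); "
                "reduce the learning rate or beta"
            )

        grads: dict[str, np.ndarray] = {}
        # decoder
        G = P.copy()
        G[np.arange(B), y] -= 1.0
        G /= B
        grads["Wd"] = G.T @ z
        grads["bd"] = G.sum(axis=0)
        g_z = G @ p["Wd"]
        # KL estimator: d(logq - logp)/dz at fixed (mu, lv, prior)
        bB = cfg.beta / B
        dlogq_dz = -zmu / var
        dlogp_dz = -np.sum(resp[:, :, None] * pdiff / pvar[None, :, :], axis=1)
        g_z = g_z + bB * (dlogq_dz - dlogp_dz)
        # latent heads: z = mu + exp(lv/2) eps, plus the explicit logq terms
        g_mu = g_z + bB * (zmu / var)
        g_lv = g_z * (0.5 * zmu) + bB * (-0.5) * (1.0 - eps * eps)
        # prior parameters (appear only through -beta * logp)
        grads["pm"] = -bB * np.einsum("bs,bsl->sl", resp, pdiff / pvar[None, :, :])
        grads["plv"] = -bB * np.einsum(
            "bs,bsl->sl", resp, -0.5 * (1.0 - pdiff * pdiff / pvar[None, :, :])
        )
        w = np.exp(logw)
        grads["pa"] = -bB * (resp - w[None, :]).sum(axis=0)
        # encoder
        grads["Wm"] = g_mu.T @ h
        grads["bm"] = g_mu.sum(axis=0)
        grads["Wv"] = g_lv.T @ h
        grads["bv"] = g_lv.sum(axis=0)
        dh = g_mu @ p["Wm"] + g_lv @ p["Wv"]
        for i in range(cfg.n_hidden - 1, -1, -1):
            da = dh * (1.0 - hs[i + 1] * hs[i + 1])
            grads[f"W{i}"] = da.T @ hs[i]
            grads[f"b{i}"] = da.sum(axis=0)
            dh = da @ p[f"W{i}"]
        self.opt.step(p, grads)
        return loss


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class SPIB:
    """SPIB model bound to a time series; ``fit()`` returns a result object.

    Parameters
    ----------
    ts:
        Multivariate CV time series; trajectories are treated independently
        when forming time-lagged prediction pairs.
    config:
        :class:`SpibConfig`; ``lag_steps`` must be shorter than the shortest
        trajectory.
    init:
        Optional initial :class:`StateLabels`; defaults to seeded k-means
        with ``config.n_initial_states`` clusters.
    """

    def __init__(self, ts: TimeSeries, config: SpibConfig, init: StateLabels | None = None):
        shortest = min(t.shape[0] for t in ts.trajectories)
        if config.lag_steps >= shortest:
            raise ValueError(
                f"lag_steps={config.lag_steps} must be smaller than the "
                f"shortest trajectory ({shortest} frames)"
            )
        self.ts = ts
        self.config = config
        self.init = init

    def fit(self, verbose: bool = False) -> "SpibResult":
        cfg = self.config
        ts = self.ts
        rng = np.random.default_rng(cfg.seed)
        X_raw = ts.pooled()
        x_mean = X_raw.mean(axis=0)
        x_std = X_raw.std(axis=0)
        x_std[x_std == 0] = 1.0
        X = (X_raw - x_mean) / x_std

        init = self.init
        if init is None:
            init = init_labels(ts, cfg.n_initial_states, seed=cfg.seed)
        y = init.pooled().copy()
        if y.max() >= cfg.n_initial_states:
            raise ValueError("initial labels exceed n_initial_states")

        src, tgt = lagged_pairs(ts, cfg.lag_steps)

        net = _SpibNet(X.shape[1], cfg, rng)
        history = {"loss": [], "label_change": [], "n_states": []}
        streak = 0
        converged = False
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(src.size)
            losses = []
            for s in range(0, order.size, cfg.batch_size):
                batch = order[s : s + cfg.batch_size]
                losses.append(net.train_step(X[src[batch]], y[tgt[batch]]))
            history["loss"].append(float(np.mean(losses)))
            if (epoch + 1) % cfg.refinement_interval == 0:
                new_y = net.predict_states(X)
                change = float(np.mean(new_y != y))
                y = new_y
                n_live = len(np.unique(y))
                history["label_change"].append(change)
                history["n_states"].append(n_live)
                if verbose:  # pragma: no cover - console output
                    print(
                        f"epoch {epoch + 1}: loss {history['loss'][-1]:.4f} "
                        f"change {change:.4f} states {n_live}"
                    )
                if n_live == 1:
                    warnings.warn("all frames collapsed to a single state")
                    converged = True
                    break
                if change < cfg.convergence_tol:
                    streak += 1
                    if streak >= cfg.patience:
                        converged = True
                        break
                else:
                    streak = 0

        y = net.predict_states(X)
        surviving = np.unique(y)
        mu = np.vstack(
            [net.encode_mean(X[s : s + 65536]) for s in range(0, X.shape[0], 65536)]
        )
        labels_per_traj, latent_per_traj = [], []
        offset = 0
        for t in ts.trajectories:
            n = t.shape[0]
            labels_per_traj.append(y[offset : offset + n])
            latent_per_traj.append(mu[offset : offset + n])
            offset += n
        labels = StateLabels(
            labels=labels_per_traj, n_states=len(surviving), latent=latent_per_traj
        )
        return SpibResult(
            params={k: v.copy() for k, v in net.params.items()},
            config=cfg,
            column_names=list(ts.column_names),
            x_mean=x_mean,
            x_std=x_std,
            labels=labels,
            surviving_states=surviving,
            history=history,
            converged=converged,
        )


@dataclass
class SpibResult:
    """Trained SPIB model: weights, schema, labels, and diagnostics."""

    params: dict
    config: SpibConfig
    column_names: list[str]
    x_mean: np.ndarray
    x_std: np.ndarray
    labels: StateLabels
    surviving_states: np.ndarray
    history: dict
    converged: bool

    @property
    def n_states(self) -> int:
        return len(self.surviving_states)

    # -- inference ---------------------------------------------------------
    def _standardize(self, features, column_names=None) -> np.ndarray:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        if column_names is not None:
            missing = [c for c in self.column_names if c not in column_names]
            if missing:
                raise ValueError(f"missing CV columns: {missing}")
            idx = [list(column_names).index(c) for c in self.column_names]
            X = X[:, idx]
        if X.shape[1] != len(self.column_names):
            raise ValueError(
                f"feature dimension {X.shape[1]} does not match the "
                f"{len(self.column_names)} training CVs {self.column_names}"
            )
        return (X - self.x_mean) / self.x_std

    def project(self, features, column_names=None):
        """Project feature vectors: (2D latent means, state posterior, argmax).

        Deterministic (uses the encoder mean).  ``features`` may be raw CV
        vectors in training column order, or any order when
        ``column_names`` is given.  Structures never seen in training (e.g.
        rows of a FeatureMatrix) can be projected the same way.
        """
        X = self._standardize(features, column_names)
        hs, mu, _ = _encode(self.params, X, self.config.n_hidden)
        logits = mu @ self.params["Wd"].T + self.params["bd"]
        posterior = np.exp(_log_softmax(logits))
        return mu, posterior, np.argmax(logits, axis=1)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "SPIB results",
            "=" * 40,
            f"CVs:                {len(self.column_names)}",
            f"lag (frames):       {self.config.lag_steps}",
            f"beta:               {self.config.beta}",
            f"initial states:     {self.config.n_initial_states}",
            f"converged:          {self.converged}",
            f"metastable states:  {self.n_states}",
        ]
        pooled = self.labels.pooled()
        for s in self.surviving_states:
            frac = np.mean(pooled == s)
            lines.append(f"  state {s}: {frac:7.2%} of frames")
        return "\n".join(lines)

    def plot_latent(self, ax=None, max_points: int = 20000):
        """Scatter of latent means colored by state (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        z = np.vstack(self.labels.latent)
        y = self.labels.pooled()
        if z.shape[0] > max_points:
            step = z.shape[0] // max_points
            z, y = z[::step], y[::step]
        for s in self.surviving_states:
            m = y == s
            ax.scatter(z[m, 0], z[m, 1], s=2, label=f"state {s}")
        ax.set_xlabel("latent 1")
        ax.set_ylabel("latent 2")
        ax.legend(markerscale=4)
        return ax

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        meta = {
            "config": asdict(self.config),
            "column_names": self.column_names,
            "surviving_states": self.surviving_states.tolist(),
            "converged": self.converged,
        }
        arrays = {f"param_{k}": v for k, v in self.params.items()}
        np.savez(
            path,
            meta=json.dumps(meta),
            x_mean=self.x_mean,
            x_std=self.x_std,
            **arrays,
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "SpibResult":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            params = {
                k[len("param_") :]: data[k] for k in data.files if k.startswith("param_")
            }
            x_mean, x_std = data["x_mean"], data["x_std"]
        cfg = SpibConfig(**meta["config"])
        empty = StateLabels(labels=[np.zeros(0, dtype=int)], n_states=len(meta["surviving_states"]))
        return cls(
            params=params,
            config=cfg,
            column_names=meta["column_names"],
            x_mean=x_mean,
            x_std=x_std,
            labels=empty,
            surviving_states=np.asarray(meta["surviving_states"]),
            history={},
            converged=meta["converged"],
        )


# ---------------------------------------------------------------------------
# Functional API
# ---------------------------------------------------------------------------

def train_spib(
    ts: TimeSeries, init: StateLabels | None, cfg: SpibConfig
) -> tuple[SpibResult, StateLabels]:
    """Train SPIB and return (trained model/result, converged labels)."""
    result = SPIB(ts, cfg, init=init).fit()
    return result, result.labels


def state_count_scan(
    ts: TimeSeries,
    cfg: SpibConfig,
    lags: list[int],
    init: StateLabels | None = None,
    seeds: list[int] | None = None,
) -> list[dict]:
    """Converged state count as a function of the lag time.

    Each lag is trained independently (the per-run seed is recorded in the
    output).  Longer lags average out fast interconversions, so the count is
    expected to be non-increasing in the lag.
    """
    if seeds is None:
        seeds = [cfg.seed] * len(lags)
    if len(seeds) != len(lags):
        raise ValueError("seeds must match lags in length")
    records = []
    for lag, seed in zip(lags, seeds):
        run_cfg = replace(cfg, lag_steps=int(lag), seed=int(seed))
        result = SPIB(ts, run_cfg, init=init).fit()
        records.append({"lag": int(lag), "n_states": result.n_states, "seed": int(seed)})
    return records
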