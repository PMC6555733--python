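"""Energy-expenditure estimators: OLS, feedforward network, recurrent network.

Three model families map inputs to metabolic power in Watts:

* :func:`fit_linear` — ordinary least squares on binned gait-cycle features,
  ``y = a^T x + b``, with no regularization or feature selection.
* :func:`fit_mlp` — a feedforward network (3-4 hidden ReLU layers of 300-1000
  units, dropout and L2 on every hidden layer, linear output) trained with a
  mean-absolute-error loss.
* :func:`fit_rnn` — two stacked LSTM layers of size 64 over 250-step
  fixed-interval windows, followed by a fully connected scalar head; trained
  with mean-squared error (evaluation elsewhere uses MAE).

The networks are implemented directly in NumPy (forward pass, manual
backpropagation, Adam optimizer).  Inputs and targets are standardized
internally; predictions are returned in Watts.  A single integer seed drives
initialization, dropout masks, and minibatch shuffling, so identical seed +
data yields identical predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "LinearModel",
    "NetworkConfig",
    "RecurrentConfig",
    "MLPRegressor",
    "LSTMRegressor",
    "fit_linear",
    "predict_linear",
    "fit_mlp",
    "fit_rnn",
]


# ---------------------------------------------------------------------------
# Linear regression
# ---------------------------------------------------------------------------

@dataclass
class LinearModel:
    """OLS estimator ``y = a^T x + b`` (minimum-norm on rank-deficient data)."""

    a: np.ndarray
    b: float
    rank: int = -1

    @property
    def n_features(self) -> int:
        return self.a.size


def fit_linear(X: np.ndarray, y: np.ndarray) -> LinearModel:
    """Ordinary least squares with intercept; no regularization.

    On a rank-deficient design the minimum-norm solution is returned and a
    warning is logged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("fit_linear needs a 2-D design with at least 2 rows")
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.shape[0]}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("design matrix and targets must be finite")
    aug = np.column_stack([X, np.ones(X.shape[0])])
    # Singular values below 1e-9 of the largest are treated as numerical rank
    # zero: such directions carry no target signal but, inverted, would amplify
    # round-off into out-of-sample noise on near-degenerate designs.
    coef, _, rank, _ = np.linalg.lstsq(aug, y, rcond=1e-9)
    if rank < aug.shape[1]:
        logger.warning("rank-deficient design (rank %d < %d columns); "
                       "minimum-norm OLS solution returned", rank, aug.shape[1])
    return LinearModel(a=coef[:-1], b=float(coef[-1]), rank=int(rank))


def predict_linear(model: LinearModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(f"X has {X.shape[1]} columns, model expects {model.n_features}")
    return X @ model.a + model.b


# ---------------------------------------------------------------------------
# Shared network machinery
# ---------------------------------------------------------------------------

@dataclass
class NetworkConfig:
    """Feedforward network hyperparameters.

    Defaults sit at the midpoints of the architecture band (3 hidden layers of
    512 ReLU units, dropout 0.2, L2 1e-4) with an Adam optimizer at learning
    rate 1e-3, batch 64, and early stopping on a 10% in-training holdout.
    """

    layer_sizes: tuple[int, ...] = (512, 512, 512)
    dropout_rate: float = 0.2
    l2_coeff: float = 1e-4
    loss: str = "mae"
    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0
    val_fraction: float = 0.10
    patience: int = 15

    def __post_init__(self) -> None:
        if not 3 <= len(self.layer_sizes) <= 4:
            raise ValueError("feedforward networks use 3 to 4 hidden layers")
        if any(not 300 <= s <= 1000 for s in self.layer_sizes):
            raise ValueError("hidden layer sizes must lie in [300, 1000]")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.l2_coeff < 0:
            raise ValueError("l2_coeff must be >= 0")
        if self.loss not in ("mae", "mse"):
            raise ValueError("loss must be 'mae' or 'mse'")


@dataclass
class RecurrentConfig:
    """Recurrent network hyperparameters: 2 LSTM layers of 64 units over
    250-step windows; MSE training loss (report with MAE for consistency)."""

    recurrent_layers: int = 2
    hidden_size: int = 64
    input_length: int = 250
    train_loss: str = "mse"
    dropout_rate: float = 0.0
    l2_coeff: float = 0.0
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    val_fraction: float = 0.0
    patience: int = 15
    clip_norm: float = 5.0


class _Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        corr1 = 1 - b1 ** self.t
        corr2 = 1 - b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + eps)


def _standardizer(X: np.ndarray, axis):
    mu = X.mean(axis=axis, keepdims=True)
    sd = X.std(axis=axis, keepdims=True)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return mu, sd


def _train_val_split(n: int, val_fraction: float, rng: np.random.Generator):
    if val_fraction <= 0 or n < 10:
        return np.arange(n), np.array([], dtype=int)
    perm = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n)))
    return perm[n_val:], perm[:n_val]


# ---------------------------------------------------------------------------
# Feedforward network
# ---------------------------------------------------------------------------

class MLPRegressor:
    """Feedforward ReLU network with dropout, L2 weight decay, and MAE loss."""

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        self.history: list[dict] = []
        self._fitted = False

    def _init_params(self, n_features: int, rng: np.random.Generator) -> None:
        sizes = [n_features, *self.cfg.layer_sizes, 1]
        self.W = [rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
                  for fan_in, fan_out in zip(sizes[:-1], sizes[1:])]
        self.b = [np.zeros(fan_out) for fan_out in sizes[1:]]

    def _forward(self, X, rng=None):
        """Forward pass; with an rng, dropout is active and caches are kept."""
        acts = [X]
        masks = []
        h = X
        keep = 1.0 - self.cfg.dropout_rate
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            if i < len(self.W) - 1:
                h = np.maximum(z, 0.0)
                if rng is not None and keep < 1.0:
                    mask = (rng.random(h.shape) < keep) / keep
                    h = h * mask
                    masks.append(mask)
                else:
                    masks.append(None)
                acts.append(h)
            else:
                h = z[:, 0]
        return h, acts, masks

    def _backward(self, dLdy, acts, masks):
        grads_W = [np.zeros_like(W) for W in self.W]
        grads_b = [np.zeros_like(b) for b in self.b]
        delta = dLdy[:, None]  # (m, 1) at the output unit
        for i in range(len(self.W) - 1, -1, -1):
            grads_W[i] = acts[i].T @ delta + 2.0 * self.cfg.l2_coeff * self.W[i]
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.W[i].T
                if masks[i - 1] is not None:
                    delta = delta * masks[i - 1]
                delta = delta * (acts[i] > 0)
        return grads_W, grads_b

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MLPRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        cfg = self.cfg
        rng = np.random.default_rng(cfg.seed)
        self._x_mu, self._x_sd = _standardizer(X, axis=0)
        self._y_mu, self._y_sd = float(y.mean()), float(y.std() or 1.0)
        Xs = (X - self._x_mu) / self._x_sd
        ys = (y - self._y_mu) / self._y_sd
        self._init_params(X.shape[1], rng)
        if hasattr(self, "_opt"):
            del self._opt

        train_idx, val_idx = _train_val_split(len(ys), cfg.val_fraction, rng)
        best_val, best_params, stale = np.inf, None, 0
        for epoch in range(cfg.epochs):
            order = rng.permutation(train_idx)
            epoch_loss = 0.0
            for start in range(0, len(order), cfg.batch_size):
                batch = order[start:start + cfg.batch_size]
                xb, yb = Xs[batch], ys[batch]
                yhat, acts, masks = self._forward(xb, rng=rng)
                resid = yhat - yb
                if cfg.loss == "mae":
                    loss = np.abs(resid).mean()
                    dLdy = np.sign(resid) / len(batch)
                else:
                    loss = (resid ** 2).mean()
                    dLdy = 2.0 * resid / len(batch)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}; inspect learning rate "
                        f"({cfg.learning_rate}) and input scaling")
                gW, gb = self._backward(dLdy, acts, masks)
                params = self.W + self.b
                if not hasattr(self, "_opt"):
                    self._opt = _Adam(params, cfg.learning_rate)
                self._opt.step(params, gW + gb)
                epoch_loss += loss * len(batch)
            epoch_loss /= max(len(order), 1)

            record = {"epoch": epoch, "train_loss": float(epoch_loss)}
            if len(val_idx):
                val_pred, _, _ = self._forward(Xs[val_idx])
                val_loss = float(np.abs(val_pred - ys[val_idx]).mean())
                record["val_loss"] = val_loss
                if val_loss < best_val - 1e-6:
                    best_val, stale = val_loss, 0
                    best_params = ([W.copy() for W in self.W], [b.copy() for b in self.b])
                else:
                    stale += 1
            self.history.append(record)
            if len(val_idx) and stale >= cfg.patience:
                logger.info("early stopping at epoch %d (best val MAE %.4f)", epoch, best_val)
                break
        if best_params is not None:
            self.W, self.b = best_params
        self._fitted = True
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("model is not fitted")
        Xs = (np.atleast_2d(np.asarray(X, dtype=float)) - self._x_mu) / self._x_sd
        yhat, _, _ = self._forward(Xs)
        return yhat * self._y_sd + self._y_mu


def fit_mlp(X: np.ndarray, y: np.ndarray, cfg: NetworkConfig | None = None) -> MLPRegressor:
    """Train the feedforward estimator; see :class:`NetworkConfig`."""
    return MLPRegressor(cfg or NetworkConfig()).fit(X, y)


# ---------------------------------------------------------------------------
# Recurrent network
# ---------------------------------------------------------------------------

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class LSTMRegressor:
    """Stacked LSTM (default 2 x 64) over fixed windows, scalar linear head.

    Training minimizes mean-squared error on standardized targets; prediction
    returns Watts.  Backpropagation through time is implemented directly; the
    global gradient norm is clipped for stability.
    """

    def __init__(self, cfg: RecurrentConfig):
        self.cfg = cfg
        self.history: list[dict] = []
        self._fitted = False

    # -- parameters ---------------------------------------------------------

    def _init_params(self, n_channels: int, rng: np.random.Generator) -> None:
        h = self.cfg.hidden_size
        self.layers = []
        in_size = n_channels
        for _ in range(self.cfg.recurrent_layers):
            scale = 1.0 / np.sqrt(in_size + h)
            Wx = rng.normal(0.0, scale, size=(in_size, 4 * h))
            Wh = rng.normal(0.0, scale, size=(h, 4 * h))
            b = np.zeros(4 * h)
            b[h:2 * h] = 1.0  # forget-gate bias: remember by default
            self.layers.append([Wx, Wh, b])
            in_size = h
        self.w_out = rng.normal(0.0, 1.0 / np.sqrt(h), size=h)
        self.b_out = 0.0

    def _params(self) -> list[np.ndarray]:
        flat = [p for layer in self.layers for p in layer]
        self._b_out_arr = np.array([self.b_out])
        return flat + [self.w_out, self._b_out_arr]

    # -- forward / backward -------------------------------------------------

    def _forward(self, X, keep_cache: bool):
        """X: (B, T, C).  Returns predictions and (optionally) caches."""
        B, T, _ = X.shape
        h_dim = self.cfg.hidden_size
        caches = []
        inputs = X
        for Wx, Wh, b in self.layers:
            h = np.zeros((B, h_dim))
            c = np.zeros((B, h_dim))
            outs = np.empty((B, T, h_dim))
            cache = []
            for t in range(T):
                x_t = inputs[:, t, :]
                z = x_t @ Wx + h @ Wh + b
                i = _sigmoid(z[:, :h_dim])
                f = _sigmoid(z[:, h_dim:2 * h_dim])
                g = np.tanh(z[:, 2 * h_dim:3 * h_dim])
                o = _sigmoid(z[:, 3 * h_dim:])
                c_prev = c
                c = f * c + i * g
                tc = np.tanh(c)
                h = o * tc
                outs[:, t, :] = h
                if keep_cache:
                    cache.append((x_t, i, f, g, o, c_prev, c, tc))
            caches.append(cache)
            inputs = outs
        yhat = inputs[:, -1, :] @ self.w_out + self.b_out
        return yhat, inputs, caches

    def _backward(self, X, dLdy, top_h, caches):
        B, T, _ = X.shape
        h_dim = self.cfg.hidden_size
        grads = [[np.zeros_like(p) for p in layer] for layer in self.layers]
        g_w_out = top_h[:, -1, :].T @ dLdy
        g_b_out = np.array([dLdy.sum()])

        # External gradient on each layer's hidden outputs per time step.
        dh_ext = np.zeros((B, T, h_dim))
        dh_ext[:, -1, :] = dLdy[:, None] * self.w_out

        for li in range(len(self.layers) - 1, -1, -1):
            Wx, Wh, b = self.layers[li]
            gWx, gWh, gb = grads[li]
            cache = caches[li]
            dx_all = np.zeros((B, T, Wx.shape[0]))
            dh_next = np.zeros((B, h_dim))
            dc_next = np.zeros((B, h_dim))
            for t in range(T - 1, -1, -1):
                x_t, i, f, g, o, c_prev, c, tc = cache[t]
                dh = dh_ext[:, t, :] + dh_next
                dc = dc_next + dh * o * (1 - tc ** 2)
                do = dh * tc
                di, dg, df = dc * g, dc * i, dc * c_prev
                dz = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                                     dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
                gWx += x_t.T @ dz
                h_prev = cache[t - 1][7] * cache[t - 1][4] if t > 0 else np.zeros_like(dh)
                # h_prev = o_{t-1} * tanh(c_{t-1})
                gWh += h_prev.T @ dz
                gb += dz.sum(axis=0)
                dh_next = dz @ Wh.T
                dc_next = dc * f
                dx_all[:, t, :] = dz @ Wx.T
            if li > 0:
                dh_ext = dx_all
        flat = [p for layer in grads for p in layer] + [g_w_out, g_b_out]
        return flat

    # -- training -----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LSTMRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        cfg = self.cfg
        if X.ndim != 3:
            raise ValueError("window tensor must be (n_windows, time, channels)")
        if X.shape[1] != cfg.input_length:
            raise ValueError(
                f"windows have {X.shape[1]} time steps; the recurrent model requires "
                f"{cfg.input_length}")
        rng = np.random.default_rng(cfg.seed)
        self._x_mu, self._x_sd = _standardizer(X.reshape(-1, X.shape[2]), axis=0)
        self._y_mu, self._y_sd = float(y.mean()), float(y.std() or 1.0)
        Xs = (X - self._x_mu) / self._x_sd
        ys = (y - self._y_mu) / self._y_sd
        self._init_params(X.shape[2], rng)

        opt = None
        train_idx, val_idx = _train_val_split(len(ys), cfg.val_fraction, rng)
        best_val, best_params, stale = np.inf, None, 0
        for epoch in range(cfg.epochs):
            order = rng.permutation(train_idx)
            epoch_loss = 0.0
            for start in range(0, len(order), cfg.batch_size):
                batch = order[start:start + cfg.batch_size]
                xb, yb = Xs[batch], ys[batch]
                yhat, top_h, caches = self._forward(xb, keep_cache=True)
                resid = yhat - yb
                loss = (resid ** 2).mean()
                if not np.isfinite(loss):
                    raise FloatingPointError(f"non-finite recurrent training loss at epoch {epoch}")
                dLdy = 2.0 * resid / len(batch)
                grads = self._backward(xb, dLdy, top_h, caches)
                norm = np.sqrt(sum(float((g ** 2).sum()) for g in grads))
                if norm > cfg.clip_norm:
                    grads = [g * (cfg.clip_norm / norm) for g in grads]
                params = self._params()
                if opt is None:
                    opt = _Adam(params, cfg.learning_rate)
                opt.step(params, grads)
                self.b_out = float(self._b_out_arr[0])
                epoch_loss += loss * len(batch)
            epoch_loss /= max(len(order), 1)
            record = {"epoch": epoch, "train_loss": float(epoch_loss)}
            if len(val_idx):
                val_pred, _, _ = self._forward(Xs[val_idx], keep_cache=False)
                val_loss = float(np.abs(val_pred - ys[val_idx]).mean())
                record["val_loss"] = val_loss
                if val_loss < best_val - 1e-6:
                    best_val, stale = val_loss, 0
                    best_params = ([[p.copy() for p in layer] for layer in self.layers],
                                   self.w_out.copy(), self.b_out)
                else:
                    stale += 1
            self.history.append(record)
            if len(val_idx) and stale >= cfg.patience:
                break
        if best_params is not None:
            self.layers, self.w_out, self.b_out = best_params
        self._fitted = True
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[1] != self.cfg.input_length:
            raise ValueError(f"windows must be (n, {self.cfg.input_length}, channels)")
        Xs = (X - self._x_mu) / self._x_sd
        yhat, _, _ = self._forward(Xs, keep_cache=False)
        return yhat * self._y_sd + self._y_mu


def _windows_to_tensor(windows) -> np.ndarray:
    if isinstance(windows, np.ndarray):
        return windows
    return np.stack([w.matrix for w in windows])


def fit_rnn(windows, y: np.ndarray, cfg: RecurrentConfig | None = None) -> LSTMRegressor:
    """Train the recurrent estimator on fixed windows (250 x C each)."""
    X = _windows_to_tensor(windows)
    return LSTMRegressor(cfg or RecurrentConfig()).fit(X, np.asarray(y, dtype=float))
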