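"""A small batched LSTM with a sigmoid output head, trained by Adam.

Implements exactly the sequence regressor the daily-risk predictor needs:
one or two stacked LSTM layers (tanh cell activations), a single
feed-forward sigmoid output unit producing a probability per time step,
mean-absolute-error loss, full-batch Adam, and early stopping on the
training loss with a configurable patience.  Forward and backward passes
are vectorised over the batch; sequences of unequal length are handled
with a per-step loss mask.

Gates are stored in the order [input, forget, output, cell-candidate] so
the three sigmoid gates occupy one contiguous block.  The backward pass is
full backpropagation through time (no truncation); only the recurrent
chain runs step by step, weight-gradient accumulation is batched over all
steps.  Gradients are verified against numerical differentiation in the
test suite.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import expit

__all__ = ["LSTMNetwork", "mae", "sigmoid"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    return expit(x)


def mae(y: np.ndarray, yhat: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Mean absolute error, optionally restricted by a boolean mask."""
    err = np.abs(np.asarray(y, float) - np.asarray(yhat, float))
    if mask is None:
        return float(err.mean())
    mask = np.asarray(mask, bool)
    return float(err[mask].mean())


class LSTMNetwork:
    """Stacked LSTM sequence regressor with a per-step sigmoid output.

    Parameters
    ----------
    n_features : input dimensionality per time step.
    hidden_units : LSTM state size (shared by both layers).
    n_layers : 1 or 2 recurrent layers.
    seed : seeds the weight initialisation; identical seeds give identical
        initial weights.
    """

    def __init__(
        self,
        n_features: int,
        hidden_units: int,
        n_layers: int = 2,
        seed: int = 0,
        dtype=np.float32,
    ):
        if n_features < 1:
            raise ValueError("n_features must be >= 1")
        if hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if n_layers not in (1, 2):
            raise ValueError("n_layers must be 1 or 2")
        self.n_features = n_features
        self.hidden = hidden_units
        self.n_layers = n_layers
        self.seed = seed
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        H = hidden_units
        self.params: dict[str, np.ndarray] = {}
        for layer in range(n_layers):
            fan_in = n_features if layer == 0 else H
            self.params[f"Wx{layer}"] = self._glorot(rng, fan_in, 4 * H, self.dtype)
            self.params[f"Wh{layer}"] = self._glorot(rng, H, 4 * H, self.dtype)
            b = np.zeros(4 * H, dtype=self.dtype)
            b[H : 2 * H] = 1.0  # forget-gate bias
            self.params[f"b{layer}"] = b
        self.params["Wy"] = self._glorot(rng, H, 1, self.dtype)
        self.params["by"] = np.zeros(1, dtype=self.dtype)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0
        self.history: list[float] = []

    @staticmethod
    def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, dtype) -> np.ndarray:
        lim = math.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=(fan_in, fan_out)).astype(dtype)

    # ------------------------------------------------------------------
    # forward / backward

    def forward(self, X: np.ndarray, cache: dict | None = None) -> np.ndarray:
        """Predict probabilities for a batch.

        ``X`` has shape (batch, T, n_features); returns (batch, T).  When
        ``cache`` is a dict it is filled with intermediates for backprop.
        """
        X = np.asarray(X, self.dtype)
        B, T, F = X.shape
        H = self.hidden
        h_in = X
        layer_caches = []
        for layer in range(self.n_layers):
            Wh = self.params[f"Wh{layer}"]
            h = np.zeros((B, H), dtype=self.dtype)
            c = np.zeros((B, H), dtype=self.dtype)
            hs = np.empty((B, T, H), dtype=self.dtype)
            gates = np.empty((B, T, 4 * H), dtype=self.dtype)  # post-activation [i, f, o, g]
            cs = np.empty((B, T, H), dtype=self.dtype)
            tcs = np.empty((B, T, H), dtype=self.dtype)
            # input contribution for every step at once
            zx = h_in @ self.params[f"Wx{layer}"] + self.params[f"b{layer}"]
            for t in range(T):
                z = zx[:, t, :] + h @ Wh
                z[:, : 3 * H] = expit(z[:, : 3 * H])
                np.tanh(z[:, 3 * H :], out=z[:, 3 * H :])
                i = z[:, :H]
                f = z[:, H : 2 * H]
                o = z[:, 2 * H : 3 * H]
                g = z[:, 3 * H :]
                c = f * c + i * g
                tc = np.tanh(c)
                h = o * tc
                gates[:, t, :] = z
                cs[:, t, :] = c
                tcs[:, t, :] = tc
                hs[:, t, :] = h
            if cache is not None:
                layer_caches.append((h_in, gates, cs, tcs, hs))
            h_in = hs
        logits = h_in @ self.params["Wy"] + self.params["by"]  # (B,T,1)
        yhat = expit(logits[..., 0])
        if cache is not None:
            cache["layers"] = layer_caches
            cache["top_h"] = h_in
            cache["yhat"] = yhat
        return yhat

    def backward(self, cache: dict, dyhat: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of the loss given d(loss)/d(yhat), shape (batch, T)."""
        yhat = cache["yhat"]
        top_h = cache["top_h"]
        B, T, H = top_h.shape
        grads: dict[str, np.ndarray] = {}
        dlogit = dyhat * yhat * (1.0 - yhat)  # (B,T)
        grads["Wy"] = (top_h.reshape(B * T, H).T @ dlogit.reshape(B * T))[:, None]
        grads["by"] = np.array([dlogit.sum()])
        dH = dlogit[..., None] * self.params["Wy"][None, None, :, 0]  # (B,T,H)
        for layer in reversed(range(self.n_layers)):
            h_in, gates, cs, tcs, hs = cache["layers"][layer]
            Wx = self.params[f"Wx{layer}"]
            Wh = self.params[f"Wh{layer}"]
            DZ = np.empty((B, T, 4 * H), dtype=self.dtype)  # pre-activation gate grads
            dh_next = np.zeros((B, H), dtype=self.dtype)
            dc_next = np.zeros((B, H), dtype=self.dtype)
            dz = np.empty((B, 4 * H), dtype=self.dtype)
            for t in reversed(range(T)):
                z = gates[:, t, :]
                i = z[:, :H]
                f = z[:, H : 2 * H]
                o = z[:, 2 * H : 3 * H]
                g = z[:, 3 * H :]
                tc = tcs[:, t, :]
                c_prev = cs[:, t - 1, :] if t > 0 else np.zeros((B, H), dtype=self.dtype)
                dh = dH[:, t, :] + dh_next
                do = dh * tc
                dc = dh * o * (1.0 - tc * tc) + dc_next
                dz[:, :H] = dc * g * i * (1.0 - i)
                dz[:, H : 2 * H] = dc * c_prev * f * (1.0 - f)
                dz[:, 2 * H : 3 * H] = do * o * (1.0 - o)
                dz[:, 3 * H :] = dc * i * (1.0 - g * g)
                dc_next = dc * f
                dh_next = dz @ Wh.T
                DZ[:, t, :] = dz
            h_prev = np.concatenate(
                [np.zeros((B, 1, H), dtype=self.dtype), hs[:, :-1, :]], axis=1
            )
            F_in = h_in.shape[2]
            grads[f"Wx{layer}"] = h_in.reshape(B * T, F_in).T @ DZ.reshape(B * T, 4 * H)
            grads[f"Wh{layer}"] = h_prev.reshape(B * T, H).T @ DZ.reshape(B * T, 4 * H)
            grads[f"b{layer}"] = DZ.sum(axis=(0, 1))
            dH = DZ @ Wx.T
        return grads

    def loss_and_grads(
        self, X: np.ndarray, Y: np.ndarray, mask: np.ndarray | None = None
    ) -> tuple[float, dict[str, np.ndarray]]:
        """MAE loss and its parameter gradients on a batch."""
        cache: dict = {}
        yhat = self.forward(X, cache=cache)
        Y = np.asarray(Y, self.dtype)
        if mask is None:
            mask = np.ones_like(Y, dtype=bool)
        n = mask.sum()
        loss = mae(Y, yhat, mask)
        dyhat = np.sign(yhat - Y) / self.dtype.type(n)
        dyhat[~mask] = 0.0
        return loss, self.backward(cache, dyhat)

    # ------------------------------------------------------------------
    # optimisation

    def adam_step(
        self,
        grads: dict[str, np.ndarray],
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self._adam_t += 1
        t = self._adam_t
        for k, p in self.params.items():
            g = grads[k]
            m = self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            v = self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    def fit(
        self,
        X: np.ndarray,
        Y: np.ndarray,
        mask: np.ndarray | None = None,
        lr: float = 0.01,
        patience: int = 50,
        max_epochs: int = 400,
    ) -> list[float]:
        """Full-batch Adam with early stopping on the training loss.

        Training stops when the loss has not decreased for ``patience``
        consecutive epochs (or at ``max_epochs``); the best-loss weights
        are restored.  Returns the per-epoch loss history.
        """
        best_loss = np.inf
        best_params = None
        stale = 0
        self.history = []
        for _ in range(max_epochs):
            loss, grads = self.loss_and_grads(X, Y, mask)
            self.history.append(loss)
            if loss < best_loss:
                best_loss = loss
                best_params = {k: v.copy() for k, v in self.params.items()}
                stale = 0
            else:
                stale += 1
                if stale >= patience:
                    break
            self.adam_step(grads, lr)
        if best_params is not None:
            self.params = best_params
        return self.history

    # ------------------------------------------------------------------
    # persistence

    def save(self, path) -> None:
        """Serialize architecture and weights to one ``.npz`` file."""
        meta = np.array(
            [self.n_features, self.hidden, self.n_layers, self.seed], dtype=np.int64
        )
        np.savez(path, __meta__=meta, __dtype__=np.array(self.dtype.str), **self.params)

    @classmethod
    def load(cls, path) -> "LSTMNetwork":
        with np.load(path) as data:
            n_features, hidden, n_layers, seed = (int(v) for v in data["__meta__"])
            net = cls(n_features, hidden, n_layers=n_layers, seed=seed,
                      dtype=np.dtype(str(data["__dtype__"])))
            net.params = {k: data[k] for k in data.files
                          if k not in ("__meta__", "__dtype__")}
        return net

    # ------------------------------------------------------------------
    # stepwise inference (for autoregressive rollout)

    def init_state(self, batch: int = 1) -> list[tuple[np.ndarray, np.ndarray]]:
        H = self.hidden
        return [(np.zeros((batch, H)), np.zeros((batch, H))) for _ in range(self.n_layers)]

    def step(
        self, x_t: np.ndarray, state: list[tuple[np.ndarray, np.ndarray]]
    ) -> tuple[np.ndarray, list[tuple[np.ndarray, np.ndarray]]]:
        """One time step: input (batch, n_features) -> probability (batch,)."""
        H = self.hidden
        h_in = np.asarray(x_t, self.dtype)
        new_state = []
        for layer in range(self.n_layers):
            h, c = state[layer]
            z = (
                h_in @ self.params[f"Wx{layer}"]
                + h @ self.params[f"Wh{layer}"]
                + self.params[f"b{layer}"]
            )
            i = expit(z[:, :H])
            f = expit(z[:, H : 2 * H])
            o = expit(z[:, 2 * H : 3 * H])
            g = np.tanh(z[:, 3 * H :])
            c = f * c + i * g
            h = o * np.tanh(c)
            new_state.append((h, c))
            h_in = h
        logits = h_in @ self.params["Wy"] + self.params["by"]
        return expit(logits[:, 0]), new_state
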