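"""A compact feed-forward regressor (NumPy, Adam) used for QSAR models and
the generator's value network.

Hidden activations: ReLU or ReLU6 (ReLU clipped at 6).  Output is either
linear or a sigmoid rescaled to a target interval, matching the convention
of bounded output activations for bounded endpoints.  Training is full-batch
or mini-batch gradient descent with Adam; weights are reproducible given the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "relu6":
        return np.clip(z, 0.0, 6.0)
    raise ValueError(f"unknown activation {name!r}")


def _act_grad(name: str, z: np.ndarray) -> np.ndarray:
    if name == "relu":
        return (z > 0).astype(z.dtype)
    if name == "relu6":
        return ((z > 0) & (z < 6)).astype(z.dtype)
    raise ValueError(f"unknown activation {name!r}")


class NumpyMLP:
    """Feed-forward regressor with Adam and He initialization."""

    def __init__(
        self,
        n_inputs: int,
        hidden_layers: tuple[int, ...] = (64, 32),
        activation: str = "relu",
        output: str = "linear",
        output_range: tuple[float, float] = (0.0, 1.0),
        learning_rate: float = 1e-3,
        seed: int = 0,
    ):
        if output not in {"linear", "sigmoid_scaled"}:
            raise ValueError(f"unknown output mode {output!r}")
        self.n_inputs = int(n_inputs)
        self.hidden_layers = tuple(int(h) for h in hidden_layers)
        self.activation = activation
        self.output = output
        self.output_range = tuple(output_range)
        self.learning_rate = float(learning_rate)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        sizes = (self.n_inputs, *self.hidden_layers, 1)
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self._adam_t = 0
        self._m = [np.zeros_like(w) for w in self.W] + [np.zeros_like(b) for b in self.b]
        self._v = [np.zeros_like(w) for w in self.W] + [np.zeros_like(b) for b in self.b]

    # -- forward -----------------------------------------------------------
    def _forward(self, X: np.ndarray):
        zs, acts = [], [X]
        a = X
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = a @ W + b
            zs.append(z)
            if i < len(self.W) - 1:
                a = _act(self.activation, z)
            else:
                a = z
            acts.append(a)
        return zs, acts

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        _, acts = self._forward(X)
        out = acts[-1][:, 0]
        if self.output == "sigmoid_scaled":
            lo, hi = self.output_range
            out = lo + (hi - lo) / (1.0 + np.exp(-np.clip(out, -60.0, 60.0)))
        return out

    # -- training ----------------------------------------------------------
    def train_batch(self, X: np.ndarray, y: np.ndarray) -> float:
        """One Adam step on the MSE of a batch; returns the batch MSE."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1)
        n = X.shape[0]
        zs, acts = self._forward(X)
        raw = acts[-1][:, 0]
        if self.output == "sigmoid_scaled":
            lo, hi = self.output_range
            sig = 1.0 / (1.0 + np.exp(-np.clip(raw, -60.0, 60.0)))
            pred = lo + (hi - lo) * sig
            dpred_draw = (hi - lo) * sig * (1.0 - sig)
        else:
            pred = raw
            dpred_draw = np.ones_like(raw)
        err = pred - y
        mse = float(np.mean(err**2))
        delta = (2.0 / n) * err * dpred_draw  # dL/draw
        grad = delta[:, None]
        gW = [np.empty(0)] * len(self.W)
        gb = [np.empty(0)] * len(self.b)
        for i in range(len(self.W) - 1, -1, -1):
            gW[i] = acts[i].T @ grad
            gb[i] = grad.sum(axis=0)
            if i > 0:
                grad = (grad @ self.W[i].T) * _act_grad(self.activation, zs[i - 1])
        self._adam_step(gW, gb)
        return mse

    def _adam_step(self, gW, gb, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        params = self.W + self.b
        grads = gW + gb
        for i, (p, g) in enumerate(zip(params, grads)):
            self._m[i] = beta1 * self._m[i] + (1 - beta1) * g
            self._v[i] = beta2 * self._v[i] + (1 - beta2) * g**2
            mhat = self._m[i] / (1 - beta1**t)
            vhat = self._v[i] / (1 - beta2**t)
            p -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int = 1000,
        batch_size: int | None = None,
        shuffle_seed: int | None = None,
    ) -> list[float]:
        """Train for ``epochs`` passes; returns the per-epoch MSE history."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1)
        n = X.shape[0]
        rng = np.random.default_rng(self.seed if shuffle_seed is None else shuffle_seed)
        history = []
        for _ in range(epochs):
            if batch_size is None or batch_size >= n:
                history.append(self.train_batch(X, y))
            else:
                order = rng.permutation(n)
                losses = []
                for start in range(0, n, batch_size):
                    idx = order[start : start + batch_size]
                    losses.append(self.train_batch(X[idx], y[idx]))
                history.append(float(np.mean(losses)))
        return history

    # -- weight transfer (target-network sync) ------------------------------
    def get_weights(self):
        return [w.copy() for w in self.W], [b.copy() for b in self.b]

    def set_weights(self, weights) -> None:
        W, b = weights
        self.W = [w.copy() for w in W]
        self.b = [bb.copy() for bb in b]

    def clone(self) -> "NumpyMLP":
        other = NumpyMLP(
            self.n_inputs,
            self.hidden_layers,
            self.activation,
            self.output,
            self.output_range,
            self.learning_rate,
            self.seed,
        )
        other.set_weights(self.get_weights())
        return other
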