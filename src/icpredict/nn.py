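"""Minimal dense neural-network regressor (NumPy).

Architecture contract: a stack of fully connected hidden layers, each
followed by ReLU and then batch normalization, ending in a single linear
output unit. Trained with Adam on MSE, mini-batches, and early stopping on
a held-out validation split. Deterministic given the seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["DenseRegressor"]

_EPS = 1e-5


class _Dense:
    def __init__(self, rng, n_in, n_out):
        # He initialization for ReLU stacks
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask

    def params(self):
        return []


class _BatchNorm:
    def __init__(self, n, momentum=0.9):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.run_mean = np.zeros(n)
        self.run_var = np.ones(n)
        self.momentum = momentum
        self.training = True

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mu
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mu, var = self.run_mean, self.run_var
        self._std = np.sqrt(var + _EPS)
        self._xhat = (x - mu) / self._std
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        m = grad.shape[0]
        self.dgamma = (grad * self._xhat).sum(axis=0)
        self.dbeta = grad.sum(axis=0)
        gx = grad * self.gamma
        return (gx - gx.mean(axis=0) - self._xhat * (gx * self._xhat).mean(axis=0)) / self._std

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class DenseRegressor:
    """MLP regressor: hidden widths per ``layer_widths``, batch norm after
    each hidden activation, one linear output neuron."""

    def __init__(
        self,
        layer_widths,
        learning_rate: float = 1e-3,
        batch_size: int = 64,
        max_epochs: int = 200,
        patience: int = 20,
        validation_fraction: float = 0.1,
        seed: int = 0,
    ):
        if not layer_widths:
            raise ValueError("layer_widths must be non-empty")
        self.layer_widths = list(layer_widths)
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.seed = seed
        self._layers = None

    def _build(self, rng, n_features):
        layers = []
        n_in = n_features
        for width in self.layer_widths:
            layers.append(_Dense(rng, n_in, width))
            layers.append(_ReLU())
            layers.append(_BatchNorm(width))
            n_in = width
        layers.append(_Dense(rng, n_in, 1))
        return layers

    def _forward(self, X, training):
        out = X
        for layer in self._layers:
            if isinstance(layer, _BatchNorm):
                layer.training = training
            out = layer.forward(out)
        return out

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1, 1)
        rng = np.random.default_rng(self.seed)
        self._layers = self._build(rng, X.shape[1])

        n = len(X)
        n_val = max(1, int(round(self.validation_fraction * n))) if n >= 10 else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if len(tr_idx) == 0:
            tr_idx = perm
            val_idx = perm[:0]
        Xtr, ytr = X[tr_idx], y[tr_idx]

        # Adam state per parameter
        params = []
        state = []
        best_val = np.inf
        best_snapshot = None
        stale = 0
        step = 0
        beta1, beta2, eps = 0.9, 0.999, 1e-8

        for epoch in range(self.max_epochs):
            order = rng.permutation(len(Xtr))
            for start in range(0, len(Xtr), self.batch_size):
                idx = order[start:start + self.batch_size]
                if len(idx) < 2:
                    continue  # batch norm needs >= 2 samples
                pred = self._forward(Xtr[idx], training=True)
                grad = 2.0 * (pred - ytr[idx]) / len(idx)
                for layer in reversed(self._layers):
                    grad = layer.backward(grad)
                step += 1
                pairs = [p for layer in self._layers for p in layer.params()]
                if not state:
                    state = [(np.zeros_like(p), np.zeros_like(p)) for p, _ in pairs]
                for (p, g), (m, v) in zip(pairs, state):
                    m *= beta1
                    m += (1 - beta1) * g
                    v *= beta2
                    v += (1 - beta2) * g * g
                    mhat = m / (1 - beta1 ** step)
                    vhat = v / (1 - beta2 ** step)
                    p -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)
                params = pairs

            if len(val_idx):
                val_pred = self._forward(X[val_idx], training=False)
                val_loss = float(np.mean((val_pred - y[val_idx]) ** 2))
                if val_loss < best_val - 1e-9:
                    best_val = val_loss
                    bn_stats = [
                        (l.run_mean.copy(), l.run_var.copy())
                        for l in self._layers if isinstance(l, _BatchNorm)
                    ]
                    best_snapshot = ([p.copy() for p, _ in params], bn_stats)
                    stale = 0
                else:
                    stale += 1
                    if stale >= self.patience:
                        break

        if best_snapshot is not None:
            saved_params, bn_stats = best_snapshot
            for (p, _), saved in zip(params, saved_params):
                p[...] = saved
            bns = [l for l in self._layers if isinstance(l, _BatchNorm)]
            for l, (mu, var) in zip(bns, bn_stats):
                l.run_mean[...] = mu
                l.run_var[...] = var
        return self

    def predict(self, X):
        if self._layers is None:
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        return self._forward(X, training=False).ravel()
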