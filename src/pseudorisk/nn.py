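"""A compact feed-forward network for pseudo-observation regression.

Architecture: fully connected dense layers, rectified-linear activations in
the hidden layers, one linear output node.  Training minimises the root
mean squared error between observed pseudo-observations and predictions
with the adaptive-moment (Adam) optimiser; if the epoch loss plateaus for
three epochs the learning rate is halved, and training stops early after
five epochs without an improvement of at least 1e-4.
"""

from __future__ import annotations

import numpy as np

__all__ = ["FeedForwardNet"]


class FeedForwardNet:
    def __init__(self, n_hidden_layers=2, n_units=30, learning_rate=0.01,
                 epochs=30, batch_size=1024, seed=0,
                 plateau_patience=3, stop_patience=5, min_improvement=1e-4):
        self.n_hidden_layers = int(n_hidden_layers)
        self.n_units = int(n_units)
        self.learning_rate = float(learning_rate)
        self.epochs = int(epochs)
        self.batch_size = int(batch_size)
        self.seed = seed
        self.plateau_patience = plateau_patience
        self.stop_patience = stop_patience
        self.min_improvement = min_improvement

    def _init_params(self, n_in, rng):
        sizes = [n_in] + [self.n_units] * self.n_hidden_layers + [1]
        self.W_ = [rng.normal(0.0, np.sqrt(2.0 / sizes[i]),
                              (sizes[i], sizes[i + 1]))
                   for i in range(len(sizes) - 1)]
        self.b_ = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]

    def _forward(self, X):
        acts = [X]
        h = X
        for i, (W, b) in enumerate(zip(self.W_, self.b_)):
            z = h @ W + b
            h = z if i == len(self.W_) - 1 else np.maximum(z, 0.0)
            acts.append(h)
        return acts

    def _backward(self, acts, resid):
        # d(MSE)/d(output) for per-batch mean of squared errors
        n = len(resid)
        grads_W, grads_b = [], []
        delta = (2.0 / n) * resid[:, None]
        for i in range(len(self.W_) - 1, -1, -1):
            grads_W.append(acts[i].T @ delta)
            grads_b.append(delta.sum(axis=0))
            if i > 0:
                delta = (delta @ self.W_[i].T) * (acts[i] > 0)
        return grads_W[::-1], grads_b[::-1]

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        rng = np.random.default_rng(self.seed)
        self._init_params(X.shape[1], rng)
        mW = [np.zeros_like(W) for W in self.W_]
        vW = [np.zeros_like(W) for W in self.W_]
        mb = [np.zeros_like(b) for b in self.b_]
        vb = [np.zeros_like(b) for b in self.b_]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        lr = self.learning_rate
        step = 0
        best = np.inf
        since_improve = 0
        since_plateau = 0
        self.loss_history_ = []
        n = len(X)
        for epoch in range(self.epochs):
            perm = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = perm[start:start + self.batch_size]
                acts = self._forward(X[idx])
                resid = acts[-1][:, 0] - y[idx]
                gW, gb = self._backward(acts, resid)
                step += 1
                for i in range(len(self.W_)):
                    mW[i] = beta1 * mW[i] + (1 - beta1) * gW[i]
                    vW[i] = beta2 * vW[i] + (1 - beta2) * gW[i] ** 2
                    mb[i] = beta1 * mb[i] + (1 - beta1) * gb[i]
                    vb[i] = beta2 * vb[i] + (1 - beta2) * gb[i] ** 2
                    mhW = mW[i] / (1 - beta1 ** step)
                    vhW = vW[i] / (1 - beta2 ** step)
                    mhb = mb[i] / (1 - beta1 ** step)
                    vhb = vb[i] / (1 - beta2 ** step)
                    self.W_[i] -= lr * mhW / (np.sqrt(vhW) + eps)
                    self.b_[i] -= lr * mhb / (np.sqrt(vhb) + eps)
            loss = float(np.sqrt(np.mean((self.predict(X) - y) ** 2)))
            self.loss_history_.append(loss)
            if loss < best - self.min_improvement:
                best = loss
                best_weights = ([W.copy() for W in self.W_],
                                [b.copy() for b in self.b_])
                since_improve = 0
                since_plateau = 0
            else:
                since_improve += 1
                since_plateau += 1
            if since_plateau >= self.plateau_patience:
                lr *= 0.5
                since_plateau = 0
            if since_improve >= self.stop_patience:
                break
        if best < np.inf:
            self.W_, self.b_ = best_weights
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return self._forward(X)[-1][:, 0]
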