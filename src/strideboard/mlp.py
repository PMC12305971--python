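"""Small fully-connected regression network trained on weighted squared error.

ReLU hidden units, a linear or ReLU output unit, Adam optimization, and
per-sample weights in the loss.  Inputs are z-scored with statistics of the
training data.  All randomness (initialization, mini-batch shuffling) comes
from one seed, so training is bit-reproducible on a fixed platform.
"""

from __future__ import annotations

import numpy as np


class MLPRegressor:
    """Weighted-MSE multilayer perceptron.

    Parameters
    ----------
    hidden_layers : tuple of int
        Hidden-layer widths, e.g. (16, 8) or (32, 16, 8).
    output_activation : {"linear", "relu"}
    learning_rate : float
        Adam step size.
    epochs, batch_size : int
        Training budget.
    seed : int
        Controls He initialization and batch shuffling.
    """

    def __init__(self, hidden_layers=(16, 8), output_activation="linear",
                 learning_rate=1e-3, epochs=300, batch_size=32, seed=0):
        if output_activation not in ("linear", "relu"):
            raise ValueError(f"unknown output activation {output_activation!r}")
        self.hidden_layers = tuple(int(h) for h in hidden_layers)
        self.output_activation = output_activation
        self.learning_rate = float(learning_rate)
        self.epochs = int(epochs)
        self.batch_size = int(batch_size)
        self.seed = int(seed)
        self.weights_: list[np.ndarray] | None = None
        self.biases_: list[np.ndarray] | None = None

    # -- internals ---------------------------------------------------------

    def _init_params(self, n_in: int, rng: np.random.Generator) -> None:
        sizes = [n_in, *self.hidden_layers, 1]
        self.weights_ = []
        self.biases_ = []
        for a, b in zip(sizes[:-1], sizes[1:]):
            self.weights_.append(rng.normal(0.0, np.sqrt(2.0 / a), size=(a, b)))
            self.biases_.append(np.zeros(b))

    def _forward(self, X: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        acts = [X]
        h = X
        last = len(self.weights_) - 1
        for i, (W, b) in enumerate(zip(self.weights_, self.biases_)):
            z = h @ W + b
            if i < last:
                h = np.maximum(z, 0.0)
            elif self.output_activation == "relu":
                h = np.maximum(z, 0.0)
            else:
                h = z
            acts.append(h)
        return h[:, 0], acts

    # -- API ---------------------------------------------------------------

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, d = X.shape
        w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float).copy()
        w = w / w.mean()

        self.x_mean_ = X.mean(axis=0)
        self.x_std_ = X.std(axis=0)
        self.x_std_[self.x_std_ == 0] = 1.0
        Xs = (X - self.x_mean_) / self.x_std_

        rng = np.random.default_rng(self.seed)
        self._init_params(d, rng)
        m = [np.zeros_like(W) for W in self.weights_] + [np.zeros_like(b) for b in self.biases_]
        v = [np.zeros_like(g) for g in m]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0

        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                yb, wb = y[idx], w[idx]
                pred, acts = self._forward(Xs[idx])
                err = pred - yb
                if not np.all(np.isfinite(pred)):
                    raise FloatingPointError(
                        f"training diverged (non-finite loss) at learning rate "
                        f"{self.learning_rate}")
                # backprop of weighted MSE: L = mean(w * err^2)
                grad_out = (2.0 * wb * err / len(idx))[:, None]
                if self.output_activation == "relu":
                    grad_out = grad_out * (acts[-1] > 0)
                grads_W, grads_b = [], []
                delta = grad_out
                for i in range(len(self.weights_) - 1, -1, -1):
                    grads_W.append(acts[i].T @ delta)
                    grads_b.append(delta.sum(axis=0))
                    if i > 0:
                        delta = (delta @ self.weights_[i].T) * (acts[i] > 0)
                grads_W.reverse()
                grads_b.reverse()

                step += 1
                params = self.weights_ + self.biases_
                grads = grads_W + grads_b
                lr_t = self.learning_rate * np.sqrt(1 - beta2**step) / (1 - beta1**step)
                for j, (p, g) in enumerate(zip(params, grads)):
                    m[j] = beta1 * m[j] + (1 - beta1) * g
                    v[j] = beta2 * v[j] + (1 - beta2) * g**2
                    p -= lr_t * m[j] / (np.sqrt(v[j]) + eps)
        return self

    def predict(self, X) -> np.ndarray:
        if self.weights_ is None:
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        Xs = (X - self.x_mean_) / self.x_std_
        pred, _ = self._forward(Xs)
        return pred

    def get_params(self) -> dict:
        return {
            "hidden_layers": list(self.hidden_layers),
            "output_activation": self.output_activation,
            "learning_rate": self.learning_rate,
            "epochs": self.epochs,
            "batch_size": self.batch_size,
            "seed": self.seed,
        }
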