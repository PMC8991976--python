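"""Minimal feed-forward neural network engine on numpy.

Implements exactly the layer types the benchmark's two deep-learning
architectures need — dense, 1D convolution (valid padding, stride 1),
batch normalisation, inverted dropout, 1D max pooling — with the Adamax
optimiser and mini-batch training with early stopping. Everything is
plain numpy, deterministic under a seed, and intentionally small: this is
not a general DL framework, just enough machinery to express a 3-stage
CNN and a 5-layer MLP and train them on one-hot genotype matrices.

Shapes: dense layers take ``(n, features)``; convolutional layers take
``(n, length, channels)``. Losses pair the output head with its natural
loss (linear/MSE, sigmoid/binary cross-entropy, softmax/categorical
cross-entropy) and backpropagate the combined, numerically stable form.
"""

from __future__ import annotations

import copy
from typing import Sequence

import numpy as np

__all__ = ["Dense", "Conv1D", "ReLU", "Dropout", "BatchNorm", "MaxPool1D",
           "Flatten", "Network"]

_BN_EPS = 1e-3
_BN_MOMENTUM = 0.99


class Layer:
    trainable: tuple[str, ...] = ()

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return [getattr(self, name) for name in self.trainable]

    def grads(self) -> list[np.ndarray]:
        return [getattr(self, "d_" + name) for name in self.trainable]

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params()))


class Dense(Layer):
    trainable = ("W", "b")

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        # He init suits the ReLU stacks; output heads start at zero so the
        # untrained net predicts the base rate / mean rather than noise
        scale = 0.0 if zero_init else np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, 1.0, size=(n_in, n_out)) * scale
        self.b = np.zeros(n_out)

    def forward(self, x, training, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.d_W = self._x.T @ grad
        self.d_b = grad.sum(axis=0)
        return grad @ self.W.T


class Conv1D(Layer):
    """Valid-padding stride-1 1D convolution over (n, length, channels) input."""

    trainable = ("W", "b")

    def __init__(self, n_in_channels: int, n_filters: int, kernel_size: int,
                 rng: np.random.Generator):
        fan_in = n_in_channels * kernel_size
        self.kernel_size = kernel_size
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(kernel_size, n_in_channels, n_filters))
        self.b = np.zeros(n_filters)

    def out_length(self, in_length: int) -> int:
        return in_length - self.kernel_size + 1

    def forward(self, x, training, rng):
        k = self.kernel_size
        if x.shape[1] < k:
            raise ValueError(f"input length {x.shape[1]} shorter than kernel {k}")
        # windows: (n, L-k+1, channels, k)
        win = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)
        self._win = win
        return np.tensordot(win, self.W, axes=([3, 2], [0, 1])) + self.b

    def backward(self, grad):
        # grad: (n, Lo, filters)
        self.d_W = np.tensordot(self._win, grad, axes=([0, 1], [0, 1])).transpose(1, 0, 2)
        self.d_b = grad.sum(axis=(0, 1))
        n, lo, _ = grad.shape
        k, c_in, _ = self.W.shape
        dwin = np.tensordot(grad, self.W, axes=(2, 2))  # (n, Lo, k, c_in)
        dx = np.zeros((n, lo + k - 1, c_in))
        for kk in range(k):
            dx[:, kk:kk + lo, :] += dwin[:, :, kk, :]
        return dx


class ReLU(Layer):
    def forward(self, x, training, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, training, rng):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class BatchNorm(Layer):
    """Batch normalisation over all axes except the last (feature/channel axis)."""

    trainable = ("gamma", "beta")

    def __init__(self, n_features: int):
        self.gamma = np.ones(n_features)
        self.beta = np.zeros(n_features)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)

    def forward(self, x, training, rng):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = _BN_MOMENTUM * self.running_mean + (1 - _BN_MOMENTUM) * mean
            self.running_var = _BN_MOMENTUM * self.running_var + (1 - _BN_MOMENTUM) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        self._xhat = (x - mean) * self._inv_std
        self._m = int(np.prod([x.shape[a] for a in axes]))
        self._training = training
        return self.gamma * self._xhat + self.beta

    def backward(self, grad):
        axes = tuple(range(grad.ndim - 1))
        self.d_gamma = (grad * self._xhat).sum(axis=axes)
        self.d_beta = grad.sum(axis=axes)
        if not self._training:
            return grad * self.gamma * self._inv_std
        m = self._m
        dxhat = grad * self.gamma
        return (self._inv_std / m) * (
            m * dxhat - dxhat.sum(axis=axes) - self._xhat * (dxhat * self._xhat).sum(axis=axes)
        )


class MaxPool1D(Layer):
    """Non-overlapping max pooling along the length axis; a trailing remainder is dropped."""

    def __init__(self, pool_size: int = 2):
        self.pool_size = pool_size

    def forward(self, x, training, rng):
        n, length, c = x.shape
        lo = length // self.pool_size
        if lo < 1:
            raise ValueError(f"input length {length} shorter than pool size {self.pool_size}")
        self._in_shape = x.shape
        xr = x[:, : lo * self.pool_size, :].reshape(n, lo, self.pool_size, c)
        self._argmax = xr.argmax(axis=2)
        return xr.max(axis=2)

    def backward(self, grad):
        n, lo, c = grad.shape
        dxr = np.zeros((n, lo, self.pool_size, c))
        ni, li, ci = np.ogrid[:n, :lo, :c]
        dxr[ni, li, self._argmax, ci] = grad
        dx = np.zeros(self._in_shape)
        dx[:, : lo * self.pool_size, :] = dxr.reshape(n, lo * self.pool_size, c)
        return dx


class Flatten(Layer):
    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


# ---------------------------------------------------------------------------
# losses (head activation fused with loss for stable gradients)
# ---------------------------------------------------------------------------


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


class _Loss:
    """Maps head logits to predictions, loss value and logit gradient."""

    def __init__(self, kind: str):
        if kind not in ("mse", "bce", "cce"):
            raise ValueError(f"unknown loss {kind!r}")
        self.kind = kind

    def activate(self, logits: np.ndarray) -> np.ndarray:
        if self.kind == "mse":
            return logits
        if self.kind == "bce":
            return _sigmoid(logits)
        return _softmax(logits)

    def value_and_grad(self, logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
        n = logits.shape[0]
        out = self.activate(logits)
        if self.kind == "mse":
            diff = out - y
            return float(np.mean(diff**2)), 2.0 * diff / diff.size
        eps = 1e-12
        if self.kind == "bce":
            loss = -np.mean(y * np.log(out + eps) + (1 - y) * np.log(1 - out + eps))
            return float(loss), (out - y) / y.size
        loss = -np.mean(np.log(out[np.arange(n), y.astype(int)] + eps))
        grad = out.copy()
        grad[np.arange(n), y.astype(int)] -= 1.0
        return float(loss), grad / n


# ---------------------------------------------------------------------------
# network + Adamax training loop
# ---------------------------------------------------------------------------


class Network:
    """Sequential network trained with Adamax and early stopping.

    ``loss`` selects the output head: ``mse`` (linear), ``bce`` (sigmoid,
    targets in {0,1}) or ``cce`` (softmax, integer class targets).
    """

    def __init__(self, layers: Sequence[Layer], loss: str, seed: int = 0,
                 learning_rate: float = 0.003):
        self.layers = list(layers)
        self.loss = _Loss(loss)
        self.learning_rate = learning_rate
        self.seed = seed
        self.history: dict[str, list[float]] = {"loss": [], "val_loss": []}
        self._adamax_state: list[tuple[np.ndarray, np.ndarray]] | None = None
        self._step = 0

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def _forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def _backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def _adamax_update(self, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        params = [p for layer in self.layers for p in layer.params()]
        grads = [g for layer in self.layers for g in layer.grads()]
        if self._adamax_state is None:
            self._adamax_state = [(np.zeros_like(p), np.zeros_like(p)) for p in params]
        self._step += 1
        bias = 1.0 - beta1**self._step
        for p, g, (m, u) in zip(params, grads, self._adamax_state):
            m *= beta1
            m += (1 - beta1) * g
            np.maximum(beta2 * u, np.abs(g), out=u)
            p -= (self.learning_rate / bias) * m / (u + eps)

    def _batch_loss(self, x: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> float:
        logits = self._forward(x, training=False, rng=rng)
        loss, _ = self.loss.value_and_grad(logits, y)
        return loss

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        batch_size: int,
        max_epochs: int = 200,
        val_fraction: float = 0.1,
        patience: int = 20,
    ) -> "Network":
        """Mini-batch training with early stopping on a validation slice.

        A ``val_fraction`` slice of the data is held out from gradient
        updates; training stops when its loss has not improved for
        ``patience`` epochs (or at ``max_epochs``), restoring the weights
        of the best epoch.
        """
        rng = np.random.default_rng(self.seed)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n = X.shape[0]
        n_val = int(round(val_fraction * n)) if val_fraction > 0 else 0
        perm = rng.permutation(n)
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        Xt, yt = X[train_idx], y[train_idx]
        Xv, yv = X[val_idx], y[val_idx]
        batch_size = max(1, min(batch_size, Xt.shape[0]))

        # the untrained net is the first restore candidate, so training can
        # never end worse (on the validation slice) than where it started
        best = self._batch_loss(Xv, yv, rng) if n_val else np.inf
        best_weights = [p.copy() for layer in self.layers for p in layer.params()]
        stale = 0
        for _ in range(max_epochs):
            order = rng.permutation(Xt.shape[0])
            epoch_loss = 0.0
            for start in range(0, Xt.shape[0], batch_size):
                idx = order[start:start + batch_size]
                logits = self._forward(Xt[idx], training=True, rng=rng)
                loss, grad = self.loss.value_and_grad(logits, yt[idx])
                self._backward(grad)
                self._adamax_update()
                epoch_loss += loss * idx.size
            epoch_loss /= Xt.shape[0]
            self.history["loss"].append(epoch_loss)
            monitor = self._batch_loss(Xv, yv, rng) if n_val else epoch_loss
            self.history["val_loss"].append(monitor)
            if monitor < best - 1e-12:
                best = monitor
                best_weights = [p.copy() for layer in self.layers for p in layer.params()]
                stale = 0
            else:
                stale += 1
                if stale >= patience:
                    break
        if best_weights is not None:
            flat = [p for layer in self.layers for p in layer.params()]
            for p, w in zip(flat, best_weights):
                p[...] = w
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Head output at inference: values (mse), probabilities (bce/cce)."""
        rng = np.random.default_rng(self.seed)
        return self.loss.activate(self._forward(np.asarray(X, dtype=float), False, rng))
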