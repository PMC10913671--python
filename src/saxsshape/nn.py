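"""Minimal 1D convolutional network toolkit (NumPy, CPU).

Implements exactly the layer types the SAXS curve encoder needs: 1D
convolutions (as a sum of shifted GEMMs, which avoids im2col copies),
non-overlapping max pooling, inverted dropout, global max pooling, dense
layers, nearest-neighbour upsampling, softmax cross-entropy and
mean-squared-error heads, and an Adam optimiser.  All tensors are float32
with channels-last layout (batch, length, channels).

Backward passes are exact gradients of the forward computation (checked
against finite differences in the test suite).
"""

from __future__ import annotations

import numpy as np

_DT = np.float32


class Layer:
    trainable = False

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self):
        return []

    def gradients(self):
        return []


class Conv1D(Layer):
    """1D convolution (cross-correlation), optional ReLU, 'valid' or 'same'.

    Weights are stored as (k, C_in, C_out); the forward pass accumulates
    x[:, t:t+Lo, :] @ W[t] over the kernel taps t.
    """

    trainable = True

    def __init__(self, c_in: int, c_out: int, kernel: int, relu: bool = True,
                 padding: str = "valid", rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.w = (rng.standard_normal((kernel, c_in, c_out)) * scale).astype(_DT)
        self.b = np.zeros(c_out, dtype=_DT)
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        self.relu = relu
        if padding not in ("valid", "same"):
            raise ValueError("padding must be 'valid' or 'same'")
        self.padding = padding
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    @property
    def n_parameters(self) -> int:
        return self.w.size + self.b.size

    def forward(self, x, train, rng):
        if self.padding == "same":
            left = (self.k - 1) // 2
            x = np.pad(x, ((0, 0), (left, self.k - 1 - left), (0, 0)))
        self._x = x
        lo = x.shape[1] - self.k + 1
        y = np.broadcast_to(self.b, (x.shape[0], lo, self.c_out)).copy()
        for t in range(self.k):
            y += x[:, t : t + lo, :] @ self.w[t]
        if self.relu:
            self._mask = y > 0
            y = np.where(self._mask, y, 0.0)
        return y

    def backward(self, grad):
        if self.relu:
            grad = np.where(self._mask, grad, 0.0)
        x = self._x
        b, lo, f = grad.shape
        gmat = grad.reshape(b * lo, f)
        self.db = gmat.sum(axis=0)
        dx = np.zeros_like(x)
        for t in range(self.k):
            xs = np.ascontiguousarray(x[:, t : t + lo, :]).reshape(b * lo, self.c_in)
            self.dw[t] = xs.T @ gmat
            dx[:, t : t + lo, :] += grad @ self.w[t].T
        if self.padding == "same":
            left = (self.k - 1) // 2
            dx = dx[:, left : x.shape[1] - (self.k - 1 - left), :]
        return dx

    def parameters(self):
        return [self.w, self.b]

    def gradients(self):
        return [self.dw, self.db]


class MaxPool1D(Layer):
    """Non-overlapping max pooling along length; a trailing remainder is dropped."""

    def __init__(self, k: int):
        self.k = k

    def forward(self, x, train, rng):
        b, length, c = x.shape
        lo = length // self.k
        self._in_len = length
        xr = x[:, : lo * self.k, :].reshape(b, lo, self.k, c)
        self._argmax = xr.argmax(axis=2)
        return xr.max(axis=2)

    def backward(self, grad):
        b, lo, c = grad.shape
        dxr = np.zeros((b, lo, self.k, c), dtype=grad.dtype)
        np.put_along_axis(dxr, self._argmax[:, :, None, :], grad[:, :, None, :], axis=2)
        dx = np.zeros((b, self._in_len, c), dtype=grad.dtype)
        dx[:, : lo * self.k, :] = dxr.reshape(b, lo * self.k, c)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate).astype(x.dtype) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class GlobalMaxPool(Layer):
    """(B, L, C) -> (B, C) max over length."""

    def forward(self, x, train, rng):
        self._shape = x.shape
        self._argmax = x.argmax(axis=1)
        return x.max(axis=1)

    def backward(self, grad):
        dx = np.zeros(self._shape, dtype=grad.dtype)
        np.put_along_axis(dx, self._argmax[:, None, :], grad[:, None, :], axis=1)
        return dx


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Reshape(Layer):
    """(B, L*C) -> (B, L, C)."""

    def __init__(self, length: int, c: int):
        self.length, self.c = length, c

    def forward(self, x, train, rng):
        return x.reshape(x.shape[0], self.length, self.c)

    def backward(self, grad):
        return grad.reshape(grad.shape[0], -1)


class Upsample1D(Layer):
    """Nearest-neighbour upsampling of the length axis by an integer factor."""

    def __init__(self, k: int):
        self.k = k

    def forward(self, x, train, rng):
        return np.repeat(x, self.k, axis=1)

    def backward(self, grad):
        b, length, c = grad.shape
        return grad.reshape(b, length // self.k, self.k, c).sum(axis=2)


class Dense(Layer):
    trainable = True

    def __init__(self, n_in: int, n_out: int, relu: bool = False,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / n_in)
        self.w = (rng.standard_normal((n_in, n_out)) * scale).astype(_DT)
        self.b = np.zeros(n_out, dtype=_DT)
        self.relu = relu

    @property
    def n_parameters(self) -> int:
        return self.w.size + self.b.size

    def forward(self, x, train, rng):
        self._x = x
        y = x @ self.w + self.b
        if self.relu:
            self._mask = y > 0
            y = np.where(self._mask, y, 0.0)
        return y

    def backward(self, grad):
        if self.relu:
            grad = np.where(self._mask, grad, 0.0)
        self.dw = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.w.T

    def parameters(self):
        return [self.w, self.b]

    def gradients(self):
        return [self.dw, self.db]


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train: bool = False, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def gradients(self):
        return [g for layer in self.layers for g in layer.gradients()]

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    probs = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean()
    grad = probs.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), (grad / n).astype(logits.dtype)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    return float(np.mean(diff**2)), (2.0 * diff / diff.size).astype(pred.dtype)


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


def train_network(
    net: Sequential,
    x: np.ndarray,
    loss_target,
    loss_fn,
    epochs: int,
    batch_size: int,
    lr: float,
    seed: int,
    verbose: bool = False,
) -> list[float]:
    """Minibatch Adam training loop; returns the per-epoch mean loss."""
    rng = np.random.default_rng(seed)
    opt = Adam(net.parameters(), lr=lr)
    n = x.shape[0]
    history: list[float] = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            out = net.forward(x[idx], train=True, rng=rng)
            loss, grad = loss_fn(out, loss_target[idx])
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, batch {start // batch_size}"
                )
            net.backward(grad)
            opt.step(net.gradients())
            losses.append(loss)
        history.append(float(np.mean(losses)))
        if verbose:
            print(f"epoch {epoch + 1}/{epochs}: loss {history[-1]:.4f}")
    return history
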