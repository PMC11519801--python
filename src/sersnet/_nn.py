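"""Minimal 1-D neural-network engine (numpy, CPU, float32).

Implements exactly the layers the spectral classifiers need — 1-D
convolution, ReLU, inverted dropout, 1-D max pooling, flatten and dense
layers with optional L2 weight decay — plus mini-batch SGD with momentum
and a reduce-on-plateau learning-rate scheduler. The output layer produces
a logit; the sigmoid is fused into the binary-cross-entropy loss for
numerical stability and applied explicitly at prediction time.

Input convention: a batch is ``(B, L)``; Conv1D promotes it to ``(B, L', F)``
with the feature/filter axis last; Flatten is row-major over (position,
filter), i.e. flat index = position * n_filters + filter.
"""

from __future__ import annotations

import numpy as np

from .errors import ShapeError

__all__ = [
    "Layer",
    "Conv1D",
    "ReLU",
    "Dropout",
    "MaxPool1D",
    "Flatten",
    "Dense",
    "Network",
    "SGDMomentum",
    "ReduceLROnPlateau",
    "sigmoid",
    "bce_with_logits",
    "bce_grad",
    "conv_output_length",
    "pool_output_length",
    "count_conv_params",
    "count_dense_params",
]

_DTYPE = np.float32


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy, computed stably from logits."""
    z = np.asarray(logits, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.mean(np.logaddexp(0.0, z) - y * z))


def bce_grad(logits: np.ndarray, y: np.ndarray) -> np.ndarray:
    """d(mean BCE)/d(logits) = (sigmoid(z) - y) / B."""
    return (sigmoid(logits) - y) / y.shape[0]


# ---------------------------------------------------------------------------
# shape arithmetic (valid convolutions, no padding)


def conv_output_length(input_len: int, kernel: int, stride: int = 1) -> int:
    """Output length of a valid (unpadded) 1-D convolution."""
    if kernel < 1 or stride < 1 or input_len < 1:
        raise ShapeError(
            f"lengths must be positive: input={input_len}, kernel={kernel}, stride={stride}"
        )
    if kernel > input_len:
        raise ShapeError(f"kernel {kernel} exceeds input length {input_len}")
    return (input_len - kernel) // stride + 1


def pool_output_length(input_len: int, pool_size: int, stride: int) -> int:
    """Output length of a valid 1-D pooling window sweep (same arithmetic)."""
    if pool_size > input_len:
        raise ShapeError(f"pool size {pool_size} exceeds input length {input_len}")
    return conv_output_length(input_len, pool_size, stride)


def count_conv_params(filters: int, kernel: int, in_channels: int = 1, bias: bool = True) -> int:
    """Trainable parameters of a Conv1D layer: filters*(kernel*in_channels [+1])."""
    if min(filters, kernel, in_channels) < 1:
        raise ShapeError("filters, kernel and in_channels must all be >= 1")
    return filters * (kernel * in_channels + (1 if bias else 0))


def count_dense_params(in_features: int, out_features: int, bias: bool = True) -> int:
    return in_features * out_features + (out_features if bias else 0)


def _glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(_DTYPE)


# ---------------------------------------------------------------------------
# layers


class Layer:
    """Base layer; stateless layers keep empty ``params``/``grads``."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def l2_penalty(self) -> float:
        return 0.0

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))


class Conv1D(Layer):
    """Valid 1-D convolution, single input channel: (B, L) -> (B, L', F)."""

    def __init__(self, filters: int, kernel: int, stride: int, rng: np.random.Generator):
        super().__init__()
        self.filters, self.kernel, self.stride = filters, kernel, stride
        self.W = _glorot_uniform(rng, (filters, kernel), fan_in=kernel, fan_out=filters)
        self.b = np.zeros(filters, dtype=_DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train, rng):
        if x.shape[1] < self.kernel:
            raise ShapeError(f"input length {x.shape[1]} < kernel {self.kernel}")
        windows = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=1)
        self._windows = windows[:, :: self.stride, :]  # (B, L', K) view
        self._in_len = x.shape[1]
        return self._windows @ self.W.T + self.b

    def backward(self, grad):
        # grad: (B, L', F)
        self.grads[0][...] = np.tensordot(grad, self._windows, axes=([0, 1], [0, 1]))
        self.grads[1][...] = grad.sum(axis=(0, 1))
        B = grad.shape[0]
        dx = np.zeros((B, self._in_len), dtype=grad.dtype)
        Lp = grad.shape[1]
        for k in range(self.kernel):
            dx[:, k : k + (Lp - 1) * self.stride + 1 : self.stride] += grad @ self.W[:, k]
        return dx


class ReLU(Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout: active in training only, identity at inference."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ShapeError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        u = rng.random(x.shape, dtype=np.float32 if x.dtype == np.float32 else np.float64)
        self._mask = (u < keep).astype(x.dtype)
        self._mask /= keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class MaxPool1D(Layer):
    """Max pooling over the position axis: (B, L, F) -> (B, L', F)."""

    def __init__(self, pool_size: int = 2, stride: int = 2):
        super().__init__()
        self.pool_size, self.stride = pool_size, stride

    def forward(self, x, train, rng):
        self._in_shape = x.shape
        B, L, F = x.shape
        Lp = pool_output_length(L, self.pool_size, self.stride)
        if self.pool_size == 2 and self.stride == 2:
            # elementwise pairwise max: the common configuration, fast path
            a = x[:, 0 : 2 * Lp : 2, :]
            b = x[:, 1 : 2 * Lp : 2, :]
            self._right = b > a  # ties keep the earlier element, like argmax
            return np.where(self._right, b, a)
        if self.stride == self.pool_size:
            # non-overlapping windows: contiguous reshape, much faster
            seg = np.ascontiguousarray(x[:, : Lp * self.pool_size, :]).reshape(
                B, Lp, self.pool_size, F
            )
            self._argmax = seg.argmax(axis=2)  # (B, Lp, F)
            return seg.max(axis=2)
        windows = np.lib.stride_tricks.sliding_window_view(x, self.pool_size, axis=1)
        windows = windows[:, :: self.stride]  # (B, L', F, P)
        self._argmax = windows.argmax(axis=-1)
        return windows.max(axis=-1)

    def backward(self, grad):
        B, Lp, F = grad.shape
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        if self.pool_size == 2 and self.stride == 2:
            right = self._right
            dx[:, 0 : 2 * Lp : 2, :] = np.where(right, 0.0, grad)
            dx[:, 1 : 2 * Lp : 2, :] = np.where(right, grad, 0.0)
            return dx
        if self.stride == self.pool_size:
            seg = np.zeros((B, Lp, self.pool_size, F), dtype=grad.dtype)
            np.put_along_axis(seg, self._argmax[:, :, None, :], grad[:, :, None, :], axis=2)
            dx[:, : Lp * self.pool_size, :] = seg.reshape(B, Lp * self.pool_size, F)
            return dx
        b_idx, p_idx, f_idx = np.indices((B, Lp, F), sparse=True)
        pos = p_idx * self.stride + self._argmax
        np.add.at(dx, (b_idx, pos, f_idx), grad)
        return dx


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class Dense(Layer):
    """Fully connected layer with optional L2 penalty on the weights."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator, l2: float = 0.0):
        super().__init__()
        self.in_features, self.out_features, self.l2 = in_features, out_features, l2
        self.W = _glorot_uniform(rng, (in_features, out_features), in_features, out_features)
        self.b = np.zeros(out_features, dtype=_DTYPE)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train, rng):
        if x.shape[1] != self.in_features:
            raise ShapeError(
                f"dense layer expects {self.in_features} features, got {x.shape[1]}"
            )
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad
        if self.l2:
            self.grads[0] += (2.0 * self.l2) * self.W
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T

    def l2_penalty(self) -> float:
        return float(self.l2 * np.sum(self.W.astype(np.float64) ** 2)) if self.l2 else 0.0


# ---------------------------------------------------------------------------
# network + optimizer


class Network:
    """A feed-forward stack ending in a single-logit output."""

    def __init__(self, layers: list[Layer], input_len: int, arch: str = "custom"):
        self.layers = layers
        self.input_len = input_len
        self.arch = arch
        self.trained = False

    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        out = x
        for layer in self.layers:
            out = layer.forward(out, train, rng)
        return out.ravel()

    def backward(self, grad_logits: np.ndarray) -> None:
        grad = grad_logits.reshape(-1, 1)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict_proba(self, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
        if X.shape[1] != self.input_len:
            raise ShapeError(
                f"model expects spectra of length {self.input_len}, got {X.shape[1]}"
            )
        X = np.asarray(X, dtype=_DTYPE)
        chunks = [
            sigmoid(self.forward(X[i : i + batch_size]))
            for i in range(0, X.shape[0], batch_size)
        ]
        return np.concatenate(chunks) if chunks else np.empty(0)

    def l2_penalty(self) -> float:
        return sum(layer.l2_penalty() for layer in self.layers)

    @property
    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"param_{i}": p for i, p in enumerate(self.parameters)}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        params = self.parameters
        if len(arrays) != len(params):
            raise ShapeError(
                f"state has {len(arrays)} arrays, model has {len(params)} parameters"
            )
        for i, p in enumerate(params):
            a = np.asarray(arrays[f"param_{i}"], dtype=p.dtype)
            if a.shape != p.shape:
                raise ShapeError(f"param_{i}: shape {a.shape} != {p.shape}")
            p[...] = a


class SGDMomentum:
    """Classic momentum SGD: v <- mu v - lr g;  w <- w + v."""

    def __init__(self, network: Network, learning_rate: float, momentum: float):
        self.network = network
        self.lr = learning_rate
        self.momentum = momentum
        self._velocity = [np.zeros_like(p) for p in network.parameters]

    def step(self) -> None:
        for v, p, g in zip(self._velocity, self.network.parameters, self.network.gradients):
            v *= self.momentum
            v -= self.lr * g
            p += v


class ReduceLROnPlateau:
    """Halve (by ``factor``) the learning rate after ``patience`` epochs
    without validation-loss improvement, never below ``min_lr``."""

    def __init__(self, optimizer: SGDMomentum, patience: int, factor: float, min_lr: float):
        self.optimizer = optimizer
        self.patience = patience
        self.factor = factor
        self.min_lr = min_lr
        self._best = np.inf
        self._wait = 0

    def step(self, val_loss: float) -> float:
        if val_loss < self._best - 1e-12:
            self._best = val_loss
            self._wait = 0
        else:
            self._wait += 1
            if self._wait >= self.patience:
                self.optimizer.lr = max(self.optimizer.lr * self.factor, self.min_lr)
                self._wait = 0
        return self.optimizer.lr
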