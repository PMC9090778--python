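"""Minimal 1D neural-network layers with explicit backpropagation.

All layers operate on float32 arrays of shape ``(batch, channels, time)``.
Each layer caches what its backward pass needs during ``forward``; a
training step is therefore forward -> backward on the same layer instances.
Parameters and their gradients live in per-layer dicts keyed by name, so an
optimizer can iterate ``layer.params`` / ``layer.grads`` generically.

The engine implements exactly the operations the spindle U-Net needs:
same-padded dilated convolution, ReLU, batch normalization, max pooling,
nearest-neighbor upsampling, channel softmax, and Adam. Gradient
correctness is enforced by a finite-difference check in the test suite.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    """Base class: parameterless layers leave ``params``/``grads`` empty."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.training = True

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1d(Layer):
    """Length-preserving ("same" zero-padded) 1D convolution with dilation.

    Weight shape is ``(out_channels, in_channels, kernel)``; the effective
    extent of the kernel is ``(kernel - 1) * dilation + 1`` samples.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int, dilation: int = 1):
        super().__init__()
        if kernel < 1 or dilation < 1:
            raise ValueError("kernel and dilation must be >= 1")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.dilation = dilation
        span = (kernel - 1) * dilation
        self.pad_left = span // 2
        self.pad_right = span - self.pad_left
        self.params = {
            "W": np.zeros((out_channels, in_channels, kernel), dtype=DTYPE),
            "b": np.zeros(out_channels, dtype=DTYPE),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cache: tuple | None = None

    @property
    def fan_in(self) -> int:
        return self.in_channels * self.kernel

    def forward(self, x: np.ndarray) -> np.ndarray:
        # Computed tap-by-tap: y += W[:, :, k] @ x_pad[:, :, k*d : k*d+T]
        # for each of the K kernel taps. K small gemms avoid the large
        # im2col intermediate, whose memory traffic dominates at T ~ 1e4.
        B, C, T = x.shape
        if C != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {C}")
        x_pad = np.pad(x, ((0, 0), (0, 0), (self.pad_left, self.pad_right)))
        K, d = self.kernel, self.dilation
        W = self.params["W"].astype(x.dtype, copy=False)
        y = np.zeros((B, self.out_channels, T), dtype=x.dtype)
        for k in range(K):
            y += np.matmul(W[:, :, k][None], x_pad[:, :, k * d : k * d + T])
        y += self.params["b"].astype(x.dtype, copy=False)[None, :, None]
        self._cache = (x_pad, T)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_pad, T = self._cache
        K, d = self.kernel, self.dilation
        W = self.params["W"].astype(dy.dtype, copy=False)
        dx_pad = np.zeros_like(x_pad, dtype=dy.dtype)
        for k in range(K):
            xs = x_pad[:, :, k * d : k * d + T]
            self.grads["W"][:, :, k] = np.matmul(dy, xs.transpose(0, 2, 1)).sum(axis=0)
            dx_pad[:, :, k * d : k * d + T] += np.matmul(W[:, :, k].T[None], dy)
        self.grads["b"][:] = dy.sum(axis=(0, 2))
        return dx_pad[:, :, self.pad_left : self.pad_left + T]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0)


class BatchNorm1d(Layer):
    """Per-channel normalization over batch and time.

    Training uses batch statistics and updates exponential running averages
    (momentum 0.1); inference uses the running averages, making forward
    passes deterministic.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params = {
            "gamma": np.ones(channels, dtype=DTYPE),
            "beta": np.zeros(channels, dtype=DTYPE),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None]) * inv_std[None, :, None]
        self._cache = (xhat, inv_std)
        return self.params["gamma"][None, :, None] * xhat + self.params["beta"][None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        B, C, T = dy.shape
        N = B * T
        self.grads["gamma"][:] = (dy * xhat).sum(axis=(0, 2))
        self.grads["beta"][:] = dy.sum(axis=(0, 2))
        dxhat = dy * self.params["gamma"][None, :, None]
        if not self.training:
            return dxhat * inv_std[None, :, None]
        s1 = dxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (inv_std[None, :, None] / N) * (N * dxhat - s1 - xhat * s2)


class MaxPool1d(Layer):
    """Non-overlapping max pooling; input length must be divisible by width."""

    def __init__(self, width: int):
        super().__init__()
        if width < 1:
            raise ValueError("pool width must be >= 1")
        self.width = width

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.width == 1:
            self._argmax = None
            return x
        B, C, T = x.shape
        if T % self.width:
            raise ValueError(f"length {T} not divisible by pool width {self.width}")
        blocks = x.reshape(B, C, T // self.width, self.width)
        self._argmax = blocks.argmax(axis=3)
        self._in_shape = x.shape
        return blocks.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.width == 1:
            return dy
        B, C, T = self._in_shape
        dx = np.zeros((B, C, T // self.width, self.width), dtype=dy.dtype)
        b, c, t = np.ogrid[:B, :C, : T // self.width]
        dx[b, c, t, self._argmax] = dy
        return dx.reshape(B, C, T)


class UpsampleNearest(Layer):
    """Nearest-neighbor temporal upsampling by an integer factor."""

    def __init__(self, factor: int):
        super().__init__()
        self.factor = factor

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.factor == 1:
            return x
        return np.repeat(x, self.factor, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.factor == 1:
            return dy
        B, C, T = dy.shape
        return dy.reshape(B, C, T // self.factor, self.factor).sum(axis=3)


class SoftmaxChannels(Layer):
    """Softmax across the channel axis; turns logits into probabilities."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        self._p = e / e.sum(axis=1, keepdims=True)
        return self._p

    def backward(self, dy: np.ndarray) -> np.ndarray:
        p = self._p
        return p * (dy - (dy * p).sum(axis=1, keepdims=True))


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def iter_layers(layer: Layer):
    """Depth-first iteration over a layer tree.

    Composite layers advertise their children via a ``children_`` list
    (``Sequential`` does so implicitly through ``layers``).
    """
    if isinstance(layer, Sequential):
        for sub in layer.layers:
            yield from iter_layers(sub)
    elif hasattr(layer, "children_"):
        for sub in layer.children_:
            yield from iter_layers(sub)
    else:
        yield layer


def set_training(root: Layer, training: bool) -> None:
    for layer in iter_layers(root):
        layer.training = training


def kaiming_uniform_(root: Layer, rng: np.random.Generator) -> None:
    """Kaiming (He) uniform initialization for ReLU networks.

    Conv weights are drawn from U(-b, b) with b = sqrt(6 / fan_in); biases
    are zeroed and batch-norm parameters reset to identity.
    """
    for layer in iter_layers(root):
        if isinstance(layer, Conv1d):
            bound = np.sqrt(6.0 / layer.fan_in)
            layer.params["W"][:] = rng.uniform(
                -bound, bound, size=layer.params["W"].shape
            ).astype(DTYPE)
            layer.params["b"][:] = 0
        elif isinstance(layer, BatchNorm1d):
            layer.params["gamma"][:] = 1
            layer.params["beta"][:] = 0
            layer.running_mean[:] = 0
            layer.running_var[:] = 1


def astype_params(root: Layer, dtype) -> None:
    """Convert all parameters, gradients and running stats to ``dtype``.

    Training runs in float32; the float64 path exists for high-precision
    verification such as finite-difference gradient checks.
    """
    for layer in iter_layers(root):
        layer.params = {k: v.astype(dtype) for k, v in layer.params.items()}
        layer.grads = {k: v.astype(dtype) for k, v in layer.grads.items()}
        if isinstance(layer, BatchNorm1d):
            layer.running_mean = layer.running_mean.astype(dtype)
            layer.running_var = layer.running_var.astype(dtype)


def parameter_count(root: Layer) -> int:
    return sum(p.size for layer in iter_layers(root) for p in layer.params.values())


def named_parameters(root: Layer):
    """Yield (key, param, grad) triples in deterministic order."""
    for i, layer in enumerate(iter_layers(root)):
        for name, p in layer.params.items():
            yield f"{i}.{type(layer).__name__}.{name}", p, layer.grads[name]


class Adam:
    """Adam stochastic gradient descent on a layer tree's parameters."""

    def __init__(
        self,
        root: Layer,
        lr: float = 0.005,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.root = root
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = {k: np.zeros_like(p) for k, p, _ in named_parameters(root)}
        self._v = {k: np.zeros_like(p) for k, p, _ in named_parameters(root)}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for k, p, g in named_parameters(self.root):
            m = self._m[k]
            v = self._v[k]
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def state_dict(root: Layer) -> dict[str, np.ndarray]:
    """Flatten all parameters and batch-norm running stats for checkpointing."""
    state: dict[str, np.ndarray] = {}
    for i, layer in enumerate(iter_layers(root)):
        for name, p in layer.params.items():
            state[f"{i}.{name}"] = p.copy()
        if isinstance(layer, BatchNorm1d):
            state[f"{i}.running_mean"] = layer.running_mean.copy()
            state[f"{i}.running_var"] = layer.running_var.copy()
    return state


def load_state_dict(root: Layer, state: dict[str, np.ndarray]) -> None:
    for i, layer in enumerate(iter_layers(root)):
        for name, p in layer.params.items():
            p[:] = state[f"{i}.{name}"]
        if isinstance(layer, BatchNorm1d):
            layer.running_mean[:] = state[f"{i}.running_mean"]
            layer.running_var[:] = state[f"{i}.running_var"]
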