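"""Minimal NumPy neural-network engine for heatmap regression.

Implements just the pieces the landmark-localization networks need:
3x3 convolutions (optionally strided or dilated) via im2col/matmul,
ReLU/sigmoid, 2x2 max-pooling, nearest-neighbour upsampling, the Adam
optimizer and an RMSE loss over heatmap pixels.  Everything is NCHW and
runs single-threaded on CPU; given a fixed seed, training is exactly
reproducible.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np

__all__ = [
    "Conv2D",
    "ReLU",
    "Sigmoid",
    "MaxPool2",
    "Upsample2",
    "Sequential",
    "Adam",
    "rmse_loss",
]


def _im2col(
    x: np.ndarray, k: int, stride: int, dilation: int, pad: int
) -> Tuple[np.ndarray, Tuple[int, int]]:
    """Unfold NCHW input into (N*Ho*Wo, C*k*k) patch rows."""
    n, c, _, _ = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    span = dilation * (k - 1) + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (span, span), axis=(2, 3))
    win = win[..., ::dilation, ::dilation]          # dilated taps -> (.., k, k)
    win = win[:, :, ::stride, ::stride]
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(cols), (ho, wo)


class Layer:
    params: Dict[str, np.ndarray]
    grads: Dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """Same-padded k x k convolution, optionally strided or dilated.

    Weight init is He-normal by default (suited to a following ReLU);
    pass ``gain`` < 2 and/or ``bias_init`` for output heads.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        stride: int = 1,
        dilation: int = 1,
        rng: Optional[np.random.Generator] = None,
        gain: float = 2.0,
        bias_init: float = 0.0,
        dtype: np.dtype = np.float32,
    ) -> None:
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd (same padding)")
        if stride > 1 and dilation > 1:
            raise ValueError("strided dilated convolution not supported")
        rng = rng if rng is not None else np.random.default_rng()
        self.k = kernel_size
        self.stride = stride
        self.dilation = dilation
        self.pad = dilation * (kernel_size - 1) // 2
        fan_in = in_channels * kernel_size * kernel_size
        w = rng.normal(0.0, np.sqrt(gain / fan_in),
                       size=(out_channels, in_channels, kernel_size, kernel_size))
        self.params = {
            "W": w.astype(dtype),
            "b": np.full(out_channels, bias_init, dtype=dtype),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cols: Optional[np.ndarray] = None
        self._x_shape: Optional[Tuple[int, ...]] = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        w, b = self.params["W"], self.params["b"]
        cols, (ho, wo) = _im2col(x, self.k, self.stride, self.dilation, self.pad)
        n = x.shape[0]
        out = cols @ w.reshape(w.shape[0], -1).T + b
        if train:
            self._cols, self._x_shape = cols, x.shape
        else:
            self._cols = None
        return out.reshape(n, ho, wo, w.shape[0]).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._cols is None or self._x_shape is None:
            raise RuntimeError("backward called before a train-mode forward")
        w = self.params["W"]
        n, cout, ho, wo = grad.shape
        dmat = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)).reshape(-1, cout)
        self.grads["W"][...] = (dmat.T @ self._cols).reshape(w.shape)
        self.grads["b"][...] = dmat.sum(axis=0)
        # input gradient: zero-stuff to input resolution, correlate with the
        # spatially flipped kernel (in/out channels swapped)
        _, cin, h, wdt = self._x_shape
        if self.stride == 1:
            stuffed = grad
        else:
            stuffed = np.zeros((n, cout, h, wdt), dtype=grad.dtype)
            stuffed[:, :, :: self.stride, :: self.stride] = grad
        w_flip = np.ascontiguousarray(
            w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        )
        back_pad = self.dilation * (self.k - 1) - self.pad
        cols, (hb, wb) = _im2col(stuffed, self.k, 1, self.dilation, back_pad)
        dx = cols @ w_flip.reshape(cin, -1).T
        self._cols = None
        return dx.reshape(n, hb, wb, cin).transpose(0, 3, 1, 2)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0.0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        with np.errstate(over="ignore"):  # exp overflow saturates to 0/1
            out = 1.0 / (1.0 + np.exp(-x))
        if train:
            self._out = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._out * (1.0 - self._out)


class InstanceNorm(Layer):
    """Per-sample, per-channel normalization over the spatial axes.

    Stateless across samples (no running statistics), so train and eval
    behave identically and runs are exactly reproducible.  Learnable
    per-channel scale (gamma) and shift (beta).
    """

    def __init__(self, channels: int, eps: float = 1e-5,
                 dtype: np.dtype = np.float32) -> None:
        super().__init__()
        self.eps = eps
        self.params = {
            "gamma": np.ones(channels, dtype=dtype),
            "beta": np.zeros(channels, dtype=dtype),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        if train:
            self._xhat, self._inv = xhat, inv
        g = self.params["gamma"][None, :, None, None]
        b = self.params["beta"][None, :, None, None]
        return g * xhat + b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        self.grads["gamma"][...] = (grad * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"][...] = grad.sum(axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        dxhat = grad * g
        m1 = dxhat.mean(axis=(2, 3), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
        return inv * (dxhat - m1 - xhat * m2)


class MaxPool2(Layer):
    """2x2 max pooling with stride 2 (requires even spatial dims)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2 requires even spatial dims, got {h}x{w}")
        blocks = (
            x.reshape(n, c, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h // 2, w // 2, 4)
        )
        idx = np.argmax(blocks, axis=-1)
        out = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._in_shape = idx, x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        blocks = np.zeros((n, c, h // 2, w // 2, 4), dtype=grad.dtype)
        np.put_along_axis(blocks, self._idx[..., None], grad[..., None], axis=-1)
        return (
            blocks.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )


class Upsample2(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = grad.shape
        return (
            grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))
        )


class Sequential:
    def __init__(self, layers: List[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self) -> List[Tuple[np.ndarray, np.ndarray]]:
        out = []
        for layer in self.layers:
            for name in layer.params:
                out.append((layer.params[name], layer.grads[name]))
        return out

    def get_state(self) -> List[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params.values()]

    def set_state(self, state: List[np.ndarray]) -> None:
        i = 0
        for layer in self.layers:
            for name in layer.params:
                layer.params[name][...] = state[i]
                i += 1
        if i != len(state):
            raise ValueError("state length does not match network parameters")


class SkipNet:
    """Small encoder-decoder with one high-resolution skip connection.

    Half-resolution stem, quarter-resolution context block (one plain and
    one dilated conv), nearest-upsampled context concatenated with the
    stem features, sigmoid head at half resolution.  The skip path is
    what gives sub-pixel localization precision: the head sees both
    context (which vertebra) and crisp half-resolution edges (where the
    corner is).  Same duck-type interface as :class:`Sequential`.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        width: int = 24,
        context_dilation: int = 2,
        rng: Optional[np.random.Generator] = None,
    ) -> None:
        rng = rng if rng is not None else np.random.default_rng()
        half = max(width // 2, 4)
        self.conv1 = Conv2D(in_channels, half, stride=2, rng=rng)
        self.norm1 = InstanceNorm(half)
        self.relu1 = ReLU()
        self.conv2 = Conv2D(half, width, stride=2, rng=rng)
        self.norm2 = InstanceNorm(width)
        self.relu2 = ReLU()
        self.conv3 = Conv2D(width, width, rng=rng)
        self.norm3 = InstanceNorm(width)
        self.relu3 = ReLU()
        self.conv4 = Conv2D(width, width, dilation=context_dilation, rng=rng)
        self.norm4 = InstanceNorm(width)
        self.relu4 = ReLU()
        self.up = Upsample2()
        self.head = Conv2D(width + half, out_channels, rng=rng, gain=1.0,
                           bias_init=-3.0)
        self.sigmoid = Sigmoid()
        self._width = width
        self._param_layers = [self.conv1, self.norm1, self.conv2, self.norm2,
                              self.conv3, self.norm3, self.conv4, self.norm4,
                              self.head]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        a1 = self.relu1.forward(
            self.norm1.forward(self.conv1.forward(x, train), train), train
        )
        a2 = self.relu2.forward(
            self.norm2.forward(self.conv2.forward(a1, train), train), train
        )
        a3 = self.relu3.forward(
            self.norm3.forward(self.conv3.forward(a2, train), train), train
        )
        a4 = self.relu4.forward(
            self.norm4.forward(self.conv4.forward(a3, train), train), train
        )
        u = self.up.forward(a4, train)
        cat = np.concatenate([u, a1], axis=1)
        return self.sigmoid.forward(self.head.forward(cat, train), train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.head.backward(self.sigmoid.backward(grad))
        g_up, g_skip = g[:, : self._width], g[:, self._width :]
        g4 = self.conv4.backward(
            self.norm4.backward(self.relu4.backward(self.up.backward(g_up)))
        )
        g3 = self.conv3.backward(
            self.norm3.backward(self.relu3.backward(g4))
        )
        g_a1 = self.conv2.backward(
            self.norm2.backward(self.relu2.backward(g3))
        ) + g_skip
        return self.conv1.backward(
            self.norm1.backward(self.relu1.backward(g_a1))
        )

    def parameters(self) -> List[Tuple[np.ndarray, np.ndarray]]:
        out = []
        for layer in self._param_layers:
            for name in layer.params:
                out.append((layer.params[name], layer.grads[name]))
        return out

    def get_state(self) -> List[np.ndarray]:
        return [p.copy() for layer in self._param_layers
                for p in layer.params.values()]

    def set_state(self, state: List[np.ndarray]) -> None:
        i = 0
        for layer in self._param_layers:
            for name in layer.params:
                layer.params[name][...] = state[i]
                i += 1
        if i != len(state):
            raise ValueError("state length does not match network parameters")


class Adam:
    """Adam optimizer with bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(
        self,
        net: Sequential,
        learning_rate: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.net = net
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p) for p, _ in net.parameters()]
        self._v = [np.zeros_like(p) for p, _ in net.parameters()]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.net.parameters()):
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            m_hat = self._m[i] / (1 - b1**self.t)
            v_hat = self._v[i] / (1 - b2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def rmse_loss(pred: np.ndarray, target: np.ndarray) -> Tuple[float, np.ndarray]:
    """Root-mean-square error over all pixels/channels, with its gradient."""
    diff = pred - target
    mse = float(np.mean(diff**2))
    loss = float(np.sqrt(mse))
    if loss == 0.0:
        return 0.0, np.zeros_like(diff)
    grad = diff / (loss * diff.size)
    return loss, grad.astype(pred.dtype)
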