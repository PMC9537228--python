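"""Minimal numpy neural-network core: layers with explicit backprop and Adam.

Layers operate on arrays of shape (N, H, W, C) — batch, time, spatial
columns, channels (NHWC). Only what the fusion network needs is implemented:
every convolution here has spatial stride equal to its spatial kernel width
(1 for pointwise-in-space kernels, J-1 for the block-strided displacement
stream), which lets im2col reduce to concatenating temporal slices of a
contiguous array, keeping the heavy lifting in BLAS.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Layer:
    """Base layer. Subclasses implement forward/backward and expose params."""

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(value, grad) pairs; grads are accumulated in place by backward."""
        return []

    def zero_grad(self) -> None:
        for _, g in self.parameters():
            g[...] = 0.0


class Conv2d(Layer):
    """2D convolution (cross-correlation) on NHWC input.

    Restrictions (all this architecture needs): temporal stride 1, spatial
    stride equal to the spatial kernel width ``kw`` (so filter placements
    tile the spatial axis in non-overlapping blocks), optional symmetric
    temporal zero-padding. Weights are stored as (out, in, kh, kw).
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: tuple[int, int],
        stride: tuple[int, int] | None = None,
        padding: tuple[int, int] = (0, 0),
        rng: np.random.Generator | None = None,
    ) -> None:
        kh, kw = kernel
        stride = stride if stride is not None else (1, kw)
        if stride[0] != 1 or stride[1] != kw:
            raise ValueError(
                f"supported strides are (1, kw); got stride={stride} for kernel={kernel}"
            )
        if padding[1] != 0:
            raise ValueError("spatial padding is not supported")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kh * kw
        bound = 1.0 / np.sqrt(fan_in)
        rng = rng or np.random.default_rng()
        self.W = rng.uniform(-bound, bound, size=(out_channels, in_channels, kh, kw)).astype(DTYPE)
        self.b = rng.uniform(-bound, bound, size=(out_channels,)).astype(DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None

    def parameters(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def output_shape(self, h: int, w: int) -> tuple[int, int]:
        kh, kw = self.kernel
        ph = self.padding[0]
        ho = h + 2 * ph - kh + 1
        if w % kw != 0:
            raise ValueError(
                f"spatial width {w} is not divisible into blocks of {kw}"
            )
        wo = w // kw
        if ho < 1:
            raise ValueError(f"input height {h} too small for temporal kernel {kh}")
        return ho, wo

    def _wmat(self) -> np.ndarray:
        # column layout is (dt, w, c); match it from (O, C, kh, kw)
        return np.ascontiguousarray(
            self.W.transpose(2, 3, 1, 0).reshape(-1, self.out_channels)
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        kh, kw = self.kernel
        ho, wo = self.output_shape(h, w)
        ph = self.padding[0]
        if ph:
            x = np.pad(x, ((0, 0), (ph, ph), (0, 0), (0, 0)))
        xr = np.ascontiguousarray(x).reshape(n, h + 2 * ph, wo, kw * c)
        cols = np.concatenate([xr[:, i : i + ho] for i in range(kh)], axis=3)
        self._cols = cols.reshape(-1, kh * kw * c)
        self._in_shape = (n, h, w, c)
        out = self._cols @ self._wmat() + self.b
        return out.reshape(n, ho, wo, self.out_channels)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        if self._cols is None:
            raise RuntimeError("backward called before forward")
        n, ho, wo, o = grad_out.shape
        kh, kw = self.kernel
        c = self.in_channels
        ph = self.padding[0]
        gmat = grad_out.reshape(-1, o)
        gw_mat = self._cols.T @ gmat            # (kh*kw*c, O)
        self.gW += gw_mat.reshape(kh, kw, c, o).transpose(3, 2, 0, 1)
        self.gb += gmat.sum(axis=0)
        dcols = (gmat @ self._wmat().T).reshape(n, ho, wo, kh, kw * c)
        hp = self._in_shape[1] + 2 * ph
        gxr = np.zeros((n, hp, wo, kw * c), dtype=grad_out.dtype)
        for i in range(kh):
            gxr[:, i : i + ho] += dcols[:, :, :, i]
        if ph:
            gxr = gxr[:, ph : hp - ph]
        return gxr.reshape(self._in_shape)

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out * self._mask


class AdaptiveMaxPool2d(Layer):
    """Max pooling to a fixed (ph, pw) output, torch-style segment bounds."""

    def __init__(self, output_size: tuple[int, int] = (1, 1)) -> None:
        self.output_size = output_size

    @staticmethod
    def _bounds(size: int, segments: int) -> list[tuple[int, int]]:
        return [
            (int(np.floor(k * size / segments)), int(np.ceil((k + 1) * size / segments)))
            for k in range(segments)
        ]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        ph, pw = self.output_size
        out = np.empty((n, ph, pw, c), dtype=x.dtype)
        self._x_shape = x.shape
        self._argmax = np.empty((n, ph, pw, c, 2), dtype=np.int64)
        hb = self._bounds(h, ph)
        wb = self._bounds(w, pw)
        for a, (h0, h1) in enumerate(hb):
            for b, (w0, w1) in enumerate(wb):
                seg = x[:, h0:h1, w0:w1, :].reshape(n, -1, c)
                flat_idx = seg.argmax(axis=1)
                out[:, a, b, :] = np.take_along_axis(seg, flat_idx[:, None, :], axis=1)[:, 0, :]
                self._argmax[:, a, b, :, 0] = h0 + flat_idx // (w1 - w0)
                self._argmax[:, a, b, :, 1] = w0 + flat_idx % (w1 - w0)
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, h, w, c = self._x_shape
        ph, pw = self.output_size
        gx = np.zeros(self._x_shape, dtype=grad_out.dtype)
        ni, ci = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
        for a in range(ph):
            for b in range(pw):
                hi = self._argmax[:, a, b, :, 0]
                wi = self._argmax[:, a, b, :, 1]
                np.add.at(gx, (ni, hi, wi, ci), grad_out[:, a, b, :])
        return gx


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None):
        bound = 1.0 / np.sqrt(in_features)
        rng = rng or np.random.default_rng()
        self.W = rng.uniform(-bound, bound, size=(out_features, in_features)).astype(DTYPE)
        self.b = rng.uniform(-bound, bound, size=(out_features,)).astype(DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def parameters(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        self.gW += grad_out.T @ self._x
        self.gb += grad_out.sum(axis=0)
        return grad_out @ self.W

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size


class ColumnGate(Layer):
    """Sigmoid-bounded multiplicative gate over the spatial (last) axis.

    The applied weight for column d is ``sigmoid(raw[d])``; the raw logits
    are trained jointly with the network and read out as importance scores.
    """

    def __init__(self, width: int) -> None:
        self.raw = np.zeros(width, dtype=DTYPE)
        self.graw = np.zeros_like(self.raw)

    def parameters(self):
        return [(self.raw, self.graw)]

    def weights(self) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.raw.astype(np.float64)))

    def forward(self, x: np.ndarray) -> np.ndarray:
        w = self.weights().astype(x.dtype)
        self._x = x
        self._w = w
        return x * w[None, None, :, None]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        w = self._w
        dw = np.einsum("nhwc,nhwc->w", grad_out, self._x, optimize=True)
        self.graw += (dw * w * (1.0 - w)).astype(DTYPE)
        return grad_out * w[None, None, :, None]


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out

    def parameters(self):
        out = []
        for layer in self.layers:
            out.extend(layer.parameters())
        return out


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilized."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, y_onehot: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy in nats plus the gradient w.r.t. the logits."""
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    loss = -np.mean(np.sum(y_onehot * np.log(np.clip(p, 1e-12, None)), axis=1))
    grad = ((p - y_onehot) / n).astype(logits.dtype)
    return float(loss), grad, p


class Adam:
    """Adaptive-moment optimizer updating parameter arrays in place."""

    def __init__(
        self,
        params: list[tuple[np.ndarray, np.ndarray]],
        lr: float = 0.003,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[...] = 0.0
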