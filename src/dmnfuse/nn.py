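"""Minimal NumPy layer library with reverse-mode gradients.

Implements exactly the pieces the fusion classifier needs: 3-D convolution
(stride 1, symmetric padding), max pooling with stride 2 and boundary-safe
ceil-mode windows, global max pooling, ReLU, dropout, linear layers, 1-D
batch normalization, a numerically stable sigmoid/BCE pair, and Adam.

Conventions
-----------
* Volumetric activations are ``(B, C, D, H, W)``; flat activations ``(B, F)``.
* ``forward(x, train=True)`` caches what ``backward`` needs; ``backward(dy)``
  returns ``dx`` and *accumulates* into ``Parameter.grad``.
* Convolution is correlation (no kernel flip), the deep-learning convention.

Every layer's gradient is checked against central finite differences in the
test suite; that check is the authority on correctness here.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

#: Cap (in elements) on the materialised im2col scratch block, so a forward
#: pass over a 91^3 grid stays well under a gigabyte.
_COL_CHUNK_ELEMS = 30_000_000


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data)
        self.grad = np.zeros_like(self.data)


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _pad_spatial(x: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return x
    width = [(0, 0), (0, 0)] + [(pad, pad)] * 3
    return np.pad(x, width)


def _iter_cols(xp: np.ndarray, k: int):
    """Yield (offset, cols) blocks of the im2col matrix of padded input `xp`.

    cols has shape (B, n_block, Cin * k^3) with rows ordered (z, y, x);
    blocks partition the z axis of the output grid.
    """
    b, c, d, h, w = xp.shape
    do, ho, wo = d - k + 1, h - k + 1, w - k + 1
    view = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    step = max(1, _COL_CHUNK_ELEMS // max(1, b * ho * wo * c * k ** 3))
    offset = 0
    for z0 in range(0, do, step):
        z1 = min(do, z0 + step)
        cols = view[:, :, z0:z1].transpose(0, 2, 3, 4, 1, 5, 6, 7)
        cols = cols.reshape(b, (z1 - z0) * ho * wo, c * k ** 3)
        yield offset, cols
        offset += cols.shape[1]


def _corr3d(x: np.ndarray, w: np.ndarray, pad: int) -> np.ndarray:
    """Correlate (B,Cin,D,H,W) with (Cout,Cin,k,k,k), stride 1."""
    k = w.shape[2]
    xp = _pad_spatial(x, pad)
    b = xp.shape[0]
    do, ho, wo = (s - k + 1 for s in xp.shape[2:])
    if min(do, ho, wo) < 1:
        raise ValueError(f"input spatial size {x.shape[2:]} too small for "
                         f"kernel {k} with padding {pad}")
    wm = w.reshape(w.shape[0], -1).T.astype(x.dtype, copy=False)
    out = np.empty((b, w.shape[0], do * ho * wo), dtype=x.dtype)
    for offset, cols in _iter_cols(xp, k):
        out[:, :, offset:offset + cols.shape[1]] = (cols @ wm).transpose(0, 2, 1)
    return out.reshape(b, w.shape[0], do, ho, wo)


class Conv3d(Layer):
    """3-D convolution, stride 1, optional symmetric zero padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 pad: int = 0, rng: np.random.Generator | None = None,
                 dtype=np.float32, need_input_grad: bool = True):
        rng = np.random.default_rng() if rng is None else rng
        fan_in = in_channels * kernel ** 3
        scale = math.sqrt(2.0 / fan_in)  # He init for the ReLU that follows
        shape = (out_channels, in_channels, kernel, kernel, kernel)
        self.w = Parameter(rng.normal(0.0, scale, shape).astype(dtype))
        self.b = Parameter(np.zeros(out_channels, dtype=dtype))
        self.kernel = kernel
        self.pad = pad
        #: set False on a network's first layer to skip the (expensive and
        #: unused) full-correlation input gradient
        self.need_input_grad = need_input_grad
        self._x: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k = self.kernel
        if not train:
            y = _corr3d(x, self.w.data, self.pad)
            y += self.b.data[None, :, None, None, None]
            return y
        self._x = x
        # build the output block-by-block and keep the im2col blocks (when
        # they fit the scratch cap) so backward need not gather them again
        xp = _pad_spatial(x, self.pad)
        b = xp.shape[0]
        do, ho, wo = (s - k + 1 for s in xp.shape[2:])
        if min(do, ho, wo) < 1:
            raise ValueError(f"input spatial size {x.shape[2:]} too small for "
                             f"kernel {k} with padding {self.pad}")
        wm = self.w.data.reshape(self.w.data.shape[0], -1).T.astype(x.dtype, copy=False)
        out = np.empty((b, self.w.data.shape[0], do * ho * wo), dtype=x.dtype)
        cache = b * do * ho * wo * xp.shape[1] * k ** 3 <= _COL_CHUNK_ELEMS
        self._cols = [] if cache else None
        for offset, cols in _iter_cols(xp, k):
            out[:, :, offset:offset + cols.shape[1]] = (cols @ wm).transpose(0, 2, 1)
            if cache:
                self._cols.append((offset, cols))
        out = out.reshape(b, self.w.data.shape[0], do, ho, wo)
        out += self.b.data[None, :, None, None, None]
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._x is not None, "backward before forward(train=True)"
        k, pad = self.kernel, self.pad
        b, cout = dy.shape[:2]
        dy_flat = dy.reshape(b, cout, -1)
        cin = self._x.shape[1]
        dw = np.zeros((cout, cin * k ** 3), dtype=self.w.data.dtype)
        blocks = self._cols if self._cols is not None else _iter_cols(
            _pad_spatial(self._x, pad), k)
        for offset, cols in blocks:
            block = dy_flat[:, :, offset:offset + cols.shape[1]]
            dw += np.einsum("bcn,bnf->cf", block, cols, optimize=True)
        self.w.grad += dw.reshape(self.w.data.shape)
        self.b.grad += dy.sum(axis=(0, 2, 3, 4))
        if not self.need_input_grad:
            return None
        # input gradient = full correlation with the flipped, transposed kernel
        w_t = np.flip(self.w.data, axis=(2, 3, 4)).transpose(1, 0, 2, 3, 4)
        return _corr3d(dy, np.ascontiguousarray(w_t), k - 1 - pad)


class MaxPool3d(Layer):
    """Max pooling with ceil-mode output size and boundary-truncated windows.

    Output size per axis is ``max(1, ceil((n - k) / s) + 1)``: the right edge
    is padded with -inf so partial windows are valid, and an input smaller
    than the kernel yields a single window covering the whole axis.
    """

    def __init__(self, kernel: int = 3, stride: int = 2):
        self.kernel = kernel
        self.stride = stride
        self._arg: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    @staticmethod
    def out_size(n: int, kernel: int, stride: int) -> int:
        return max(1, -(-(n - kernel) // stride) + 1)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, s = self.kernel, self.stride
        b, c = x.shape[:2]
        spatial = x.shape[2:]
        out_sp = tuple(self.out_size(n, k, s) for n in spatial)
        need = tuple((o - 1) * s + k for o in out_sp)
        if need != spatial:
            width = [(0, 0), (0, 0)] + [(0, nd - n) for nd, n in zip(need, spatial)]
            xp = np.pad(x, width, constant_values=-np.inf)
        else:
            xp = x
        view = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))[:, :, ::s, ::s, ::s]
        windows = view.reshape(b, c, *out_sp, k ** 3)
        arg = windows.argmax(axis=-1)
        out = np.take_along_axis(windows, arg[..., None], axis=-1)[..., 0]
        if train:
            self._arg = arg
            self._shape = x.shape
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        assert self._arg is not None and self._shape is not None
        k, s = self.kernel, self.stride
        dx = np.zeros(self._shape, dtype=dy.dtype)
        lz, ly, lx = np.unravel_index(self._arg, (k, k, k))
        bi, ci, iz, iy, ix = np.indices(self._arg.shape, sparse=True)
        np.add.at(dx, (bi, ci, iz * s + lz, iy * s + ly, ix * s + lx), dy)
        return dx


class GlobalMaxPool3d(Layer):
    """Collapse all spatial dimensions by max, yielding (B, C)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        flat = x.reshape(x.shape[0], x.shape[1], -1)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        if train:
            self._arg = arg
            self._shape = x.shape
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c = dy.shape
        dx = np.zeros((b, c, int(np.prod(self._shape[2:]))), dtype=dy.dtype)
        bi, ci = np.indices((b, c), sparse=True)
        dx[bi, ci, self._arg] = dy
        return dx.reshape(self._shape)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode. Needs `rng` set to drop."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0.0:
            self._mask = None
            return x
        rng = self.rng if self.rng is not None else np.random.default_rng()
        self._mask = (rng.random(x.shape) >= self.p).astype(x.dtype) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = np.random.default_rng() if rng is None else rng
        scale = math.sqrt(2.0 / in_features)
        self.w = Parameter(rng.normal(0.0, scale, (out_features, in_features)).astype(dtype))
        self.b = Parameter(np.zeros(out_features, dtype=dtype))

    def parameters(self) -> list[Parameter]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w.data.T + self.b.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.data


class BatchNorm1d(Layer):
    """Batch normalization over feature vectors (B, F), with running stats."""

    def __init__(self, num_features: int, momentum: float = 0.1,
                 eps: float = 1e-5, dtype=np.float32):
        self.gamma = Parameter(np.ones(num_features, dtype=dtype))
        self.beta = Parameter(np.zeros(num_features, dtype=dtype))
        self.running_mean = np.zeros(num_features, dtype=dtype)
        self.running_var = np.ones(num_features, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            n = x.shape[0]
            unbiased = var * n / max(1, n - 1)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(
                self.running_mean.dtype)
            self.running_var = ((1 - m) * self.running_var + m * unbiased).astype(
                self.running_var.dtype)
            self._inv_std = 1.0 / np.sqrt(var + self.eps)
            self._xhat = (x - mean) * self._inv_std
            return self.gamma.data * self._xhat + self.beta.data
        inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
        return self.gamma.data * (x - self.running_mean) * inv_std + self.beta.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._xhat, self._inv_std
        self.gamma.grad += (dy * xhat).sum(axis=0)
        self.beta.grad += dy.sum(axis=0)
        n = dy.shape[0]
        dxhat = dy * self.gamma.data
        return (inv_std / n) * (n * dxhat - dxhat.sum(axis=0)
                                - xhat * (dxhat * xhat).sum(axis=0))


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
            if dy is None:  # a layer opted out of input gradients
                break
        return dy


# ---------------------------------------------------------------------------
# activations, loss, optimizer
# ---------------------------------------------------------------------------

def sigmoid(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def binary_cross_entropy(prob, label, eps: float = 1e-7):
    """Elementwise BCE with probabilities clamped to [eps, 1 - eps]."""
    p = np.clip(np.asarray(prob, dtype=float), eps, 1.0 - eps)
    y = np.asarray(label, dtype=float)
    return -(y * np.log(p) + (1.0 - y) * np.log1p(-p))


class Adam:
    def __init__(self, params: Sequence[Parameter], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
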