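"""A minimal numpy neural-network engine for the tracker and U-Nets.

Implements exactly the layers the pipeline's architectures need — 3D and 2D
"same"-padded convolutions, (2,2,1)/(2,2) max pooling, dense layers, ReLU,
dropout, nearest-neighbour upsampling with skip concatenation — together
with explicit backpropagation, an Adam optimizer, mean-squared-error and
per-pixel weighted cross-entropy losses, and ``.npz`` checkpointing.

Convolutions are computed as a sum of shifted matrix products (one matmul
per kernel offset), which keeps both forward and backward passes inside
BLAS.  Everything is float32 and deterministic given the ``numpy``
``Generator`` passed in at construction / training time.

Tensor layouts: 3D convolutions use ``(B, H, W, T, C)`` — no pooling is
ever applied along the temporal axis ``T`` — and 2D convolutions use
``(B, H, W, C)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Param", "Adam", "Conv3d", "Conv2d", "MaxPool3d221", "MaxPool2d22",
    "Dense", "Dropout", "ReLU", "mse_loss", "weighted_bce_loss", "sigmoid",
]


class Param:
    """A trainable tensor with its gradient and Adam moments."""

    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


class Adam:
    """Adam optimizer over a flat list of :class:`Param`."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p in self.params:
            p.m *= b1
            p.m += (1 - b1) * p.grad
            p.v *= b2
            p.v += (1 - b2) * p.grad ** 2
            p.value -= self.lr * (p.m / bias1) / (np.sqrt(p.v / bias2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


def _he(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

def _im2col3(x: np.ndarray, k: int) -> np.ndarray:
    """Zero-pad (B,H,W,T,C) for "same" output and unfold k^3 windows into
    rows of a 2D matrix ordered (i, j, l, c)."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0)))
    view = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k),
                                                    axis=(1, 2, 3))
    # view: (B, H, W, T, C, k, k, k) -> rows (B*H*W*T, k^3*C)
    b, h, w, t = x.shape[:4]
    return view.transpose(0, 1, 2, 3, 5, 6, 7, 4).reshape(
        b * h * w * t, k ** 3 * x.shape[4])


def _im2col2(x: np.ndarray, k: int) -> np.ndarray:
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
    view = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    b, h, w = x.shape[:3]
    return view.transpose(0, 1, 2, 4, 5, 3).reshape(
        b * h * w, k * k * x.shape[3])


class Conv3d:
    """k x k x k "same" convolution over (B, H, W, T, C).

    Forward and both backward products are single BLAS matmuls on an
    im2col matrix; the input gradient is the correlation of the output
    gradient with the flipped kernel.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 k: int = 3):
        self.k = k
        fan_in = k * k * k * c_in
        self.w = Param(_he(rng, (k, k, k, c_in, c_out), fan_in))
        self.b = Param(np.zeros(c_out, dtype=np.float32))
        self._cols = None
        self._xshape = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.k
        co = self.w.value.shape[-1]
        self._xshape = x.shape
        self._cols = _im2col3(x, k)
        out = self._cols @ self.w.value.reshape(-1, co) + self.b.value
        return out.reshape(x.shape[:4] + (co,))

    def backward(self, g: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        ci, co = self.w.value.shape[3:]
        gm = g.reshape(-1, co)
        self.w.grad += (self._cols.T @ gm).reshape(self.w.value.shape)
        self.b.grad += gm.sum(axis=0)
        self._cols = None
        # fold dcols back onto the padded input grid
        b, h, w, t = self._xshape[:4]
        dcols = (gm @ self.w.value.reshape(-1, co).T).reshape(
            b, h, w, t, k, k, k, ci)
        dxp = np.zeros((b, h + 2 * p, w + 2 * p, t + 2 * p, ci),
                       dtype=g.dtype)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    dxp[:, i:i + h, j:j + w, l:l + t] += dcols[..., i, j, l, :]
        return dxp[:, p:p + h, p:p + w, p:p + t, :]


class Conv2d:
    """k x k "same" convolution over (B, H, W, C); k = 1 or 3."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 k: int = 3):
        self.k = k
        self.w = Param(_he(rng, (k, k, c_in, c_out), k * k * c_in))
        self.b = Param(np.zeros(c_out, dtype=np.float32))
        self._cols = None
        self._xshape = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        co = self.w.value.shape[-1]
        self._xshape = x.shape
        self._cols = _im2col2(x, self.k)
        out = self._cols @ self.w.value.reshape(-1, co) + self.b.value
        return out.reshape(x.shape[:3] + (co,))

    def backward(self, g: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        ci, co = self.w.value.shape[2:]
        gm = g.reshape(-1, co)
        self.w.grad += (self._cols.T @ gm).reshape(self.w.value.shape)
        self.b.grad += gm.sum(axis=0)
        self._cols = None
        b, h, w = self._xshape[:3]
        dcols = (gm @ self.w.value.reshape(-1, co).T).reshape(
            b, h, w, k, k, ci)
        if p == 0:
            return dcols.reshape(self._xshape)
        dxp = np.zeros((b, h + 2 * p, w + 2 * p, ci), dtype=g.dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + h, j:j + w] += dcols[..., i, j, :]
        return dxp[:, p:p + h, p:p + w, :]


class MaxPool3d221:
    """(2, 2, 1) max pooling: halves H and W, never pools along time."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, h, w, t, c = x.shape
        xr = x.reshape(b, h // 2, 2, w // 2, 2, t, c)
        xr = xr.transpose(0, 1, 3, 5, 6, 2, 4).reshape(
            b, h // 2, w // 2, t, c, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, g: np.ndarray) -> np.ndarray:
        b, h, w, t, c = self._shape
        out = np.zeros((b, h // 2, w // 2, t, c, 4), dtype=g.dtype)
        np.put_along_axis(out, self._idx[..., None], g[..., None], axis=-1)
        out = out.reshape(b, h // 2, w // 2, t, c, 2, 2)
        out = out.transpose(0, 1, 5, 2, 6, 3, 4).reshape(b, h, w, t, c)
        return out


class MaxPool2d22:
    def forward(self, x: np.ndarray) -> np.ndarray:
        b, h, w, c = x.shape
        xr = x.reshape(b, h // 2, 2, w // 2, 2, c)
        xr = xr.transpose(0, 1, 3, 5, 2, 4).reshape(b, h // 2, w // 2, c, 4)
        self._idx = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, g: np.ndarray) -> np.ndarray:
        b, h, w, c = self._shape
        out = np.zeros((b, h // 2, w // 2, c, 4), dtype=g.dtype)
        np.put_along_axis(out, self._idx[..., None], g[..., None], axis=-1)
        out = out.reshape(b, h // 2, w // 2, c, 2, 2)
        out = out.transpose(0, 1, 4, 2, 5, 3).reshape(b, h, w, c)
        return out


def upsample2x(x: np.ndarray) -> np.ndarray:
    """Nearest-neighbour 2x upsampling of (B, H, W, C)."""
    return x.repeat(2, axis=1).repeat(2, axis=2)


def upsample2x_backward(g: np.ndarray) -> np.ndarray:
    b, h, w, c = g.shape
    return g.reshape(b, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = Param(_he(rng, (n_in, n_out), n_in))
        self.b = Param(np.zeros(n_out, dtype=np.float32))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        out = g @ self.w.value.T
        self._x = None
        return out


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        out = g * self._mask
        self._mask = None
        return out


class Dropout:
    """Inverted dropout; identity when ``train`` is false or rng is None."""

    def __init__(self, p: float):
        self.p = p
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        if not train or rng is None or self.p <= 0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return g
        out = g * self._mask
        self._mask = None
        return out


# ---------------------------------------------------------------------------
# Losses and metrics
# ---------------------------------------------------------------------------

def mse_loss(pred: np.ndarray, truth: np.ndarray):
    """Mean squared error and its gradient wrt ``pred``."""
    diff = pred - truth
    loss = float(np.mean(diff ** 2))
    return loss, (2.0 / diff.size) * diff


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def weighted_bce_loss(logits: np.ndarray, target: np.ndarray,
                      weight: np.ndarray):
    """Per-pixel weighted binary cross-entropy on logits.

    Returns ``(loss, dloss/dlogits)``; the loss is the weighted mean over
    all pixels (weights normalized by their sum).
    """
    z, y, w = logits, target, weight
    wsum = float(w.sum()) or 1.0
    # stable: max(z,0) - z*y + log1p(exp(-|z|))
    per = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    loss = float((w * per).sum() / wsum)
    grad = w * (sigmoid(z) - y) / wsum
    return loss, grad


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_arrays(path, spec_dict: dict, params) -> None:
    """Save a model checkpoint: spec metadata (JSON) + parameter arrays."""
    arrays = {f"p{i}": p.value for i, p in enumerate(params)}
    np.savez(path, spec=np.frombuffer(
        json.dumps(spec_dict).encode(), dtype=np.uint8), **arrays)


def load_arrays(path):
    """Load a checkpoint; returns ``(spec_dict, list_of_arrays)``."""
    data = np.load(path)
    spec = json.loads(bytes(data["spec"]).decode())
    n = len([k for k in data.files if k.startswith("p")])
    return spec, [data[f"p{i}"] for i in range(n)]


def get_state(params) -> list[np.ndarray]:
    return [p.value.copy() for p in params]


def set_state(params, state) -> None:
    for p, s in zip(params, state, strict=True):
        p.value[...] = s
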