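"""Minimal CPU tensor layers with hand-written backprop.

Just enough machinery for a small fully-convolutional detector: 2-d
convolution (im2col + GEMM), ReLU, 3x3 max pooling, an Adam optimizer with
L2 weight decay, and a versioned ``.npz`` checkpoint container.  All
activations are float32 ``(C, H, W)`` arrays (single image per step).
"""

from __future__ import annotations

import numpy as np

CHECKPOINT_VERSION = 1


class Param:
    __slots__ = ("data", "grad", "frozen")

    def __init__(self, data: np.ndarray):
        self.data = data.astype(np.float32)
        self.grad = np.zeros_like(self.data)
        self.frozen = False


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """(C,H,W) -> columns (C*kh*kw, OH*OW) plus output shape."""
    c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    view = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(1, 2))
    view = view[:, ::stride, ::stride]               # (C, OH, OW, kh, kw)
    cols = view.transpose(0, 3, 4, 1, 2).reshape(c * kh * kw, oh * ow)
    return np.ascontiguousarray(cols), oh, ow


def _col2im(dcols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    """Scatter-add column gradients back to the (C,H,W) input gradient."""
    c, h, w = x_shape
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    dxp = np.zeros((c, h + 2 * pad, w + 2 * pad), dtype=np.float32)
    d = dcols.reshape(c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            dxp[:, i:i + stride * oh:stride, j:j + stride * ow:stride] += d[:, i, j]
    if pad:
        return dxp[:, pad:h + pad, pad:w + pad]
    return dxp


class Conv2d(Layer):
    """kxk convolution, stride s, symmetric zero padding (default k//2)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int | None = None):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride = kernel, stride
        self.pad = kernel // 2 if pad is None else pad
        self.weight = Param(np.zeros((out_ch, in_ch, kernel, kernel), np.float32))
        self.bias = Param(np.zeros(out_ch, np.float32))
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x):
        cols, oh, ow = _im2col(x, self.kernel, self.kernel, self.stride, self.pad)
        wmat = self.weight.data.reshape(self.out_ch, -1)
        out = wmat @ cols + self.bias.data[:, None]
        self._cache = (x.shape, cols)
        return out.reshape(self.out_ch, oh, ow)

    def backward(self, dout):
        x_shape, cols = self._cache
        dmat = dout.reshape(self.out_ch, -1).astype(np.float32)
        self.weight.grad += (dmat @ cols.T).reshape(self.weight.data.shape)
        self.bias.grad += dmat.sum(axis=1)
        wmat = self.weight.data.reshape(self.out_ch, -1)
        dcols = wmat.T @ dmat
        return _col2im(dcols, x_shape, self.kernel, self.kernel,
                       self.stride, self.pad)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dout):
        return np.where(self._mask, dout, 0.0).astype(np.float32)


class MaxPool2d(Layer):
    """Overlapping max pooling (kernel 3, stride 2 by default)."""

    def __init__(self, kernel: int = 3, stride: int = 2, pad: int = 1):
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self._cache = None

    def forward(self, x):
        k, s, p = self.kernel, self.stride, self.pad
        cols, oh, ow = _im2col(x, k, k, s, p)
        c = x.shape[0]
        cols = cols.reshape(c, k * k, oh * ow)
        arg = cols.argmax(axis=1)
        out = np.take_along_axis(cols, arg[:, None, :], axis=1)[:, 0, :]
        self._cache = (x.shape, arg, oh, ow)
        return out.reshape(c, oh, ow).astype(np.float32)

    def backward(self, dout):
        x_shape, arg, oh, ow = self._cache
        c = x_shape[0]
        k = self.kernel
        dcols = np.zeros((c, k * k, oh * ow), dtype=np.float32)
        np.put_along_axis(dcols, arg[:, None, :],
                          dout.reshape(c, 1, oh * ow).astype(np.float32), axis=1)
        return _col2im(dcols.reshape(c * k * k, oh * ow), x_shape, k, k,
                       self.stride, self.pad)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


def init_gaussian(params: list[Param], std: float = 0.01, seed: int = 0) -> None:
    """Draw every weight from N(0, std^2); biases stay zero.

    The RNG seed is explicit so initialization is reproducible.
    """
    rng = np.random.default_rng(seed)
    for p in params:
        if p.data.ndim > 1:  # weights
            p.data[...] = rng.normal(0.0, std, size=p.data.shape)
        else:                # biases
            p.data[...] = 0.0
        p.grad[...] = 0.0


# magnitudes below this are flushed to exact zero in optimizer state and
# weights: geometric decay of Adam's moments for dead units otherwise
# drifts into float32 subnormal range within ~10^3 steps, and subnormal
# arithmetic runs orders of magnitude slower on x86
DENORMAL_FLOOR = 1e-30


def flush_subnormals(arr: np.ndarray) -> None:
    """In-place: zero every element with magnitude below DENORMAL_FLOOR."""
    arr *= np.abs(arr) > DENORMAL_FLOOR


class Adam:
    """Adam with first-moment decay beta1 and L2 weight decay on weights."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.frozen:
                continue
            g = p.grad
            if self.weight_decay and p.data.ndim > 1:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            flush_subnormals(self.m[i])
            flush_subnormals(self.v[i])
            flush_subnormals(p.data)


def save_checkpoint(path, named_params: dict[str, Param], meta: dict | None = None):
    """Write parameters to a single-file name->array archive with a version."""
    arrays = {f"param/{k}": p.data for k, p in named_params.items()}
    arrays["version"] = np.asarray(CHECKPOINT_VERSION)
    if meta:
        for k, v in meta.items():
            arrays[f"meta/{k}"] = np.asarray(v)
    np.savez(path, **arrays)


def load_checkpoint(path, named_params: dict[str, Param]) -> dict:
    with np.load(path, allow_pickle=False) as z:
        if int(z["version"]) != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {int(z['version'])}")
        for k, p in named_params.items():
            arr = z[f"param/{k}"]
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data[...] = arr
        return {k[5:]: z[k] for k in z.files if k.startswith("meta/")}
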