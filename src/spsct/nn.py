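"""Minimal NumPy neural-network core: 2-D convolution, ReLU, 2x2 max
pooling/unpooling with shared switch indices, and Adam.

Written for the dual-frame U-Net in :mod:`spsct.artifact_net`. Everything
is explicit forward/backward NumPy so training is bit-reproducible under a
seed — there is no threading or kernel nondeterminism to control for.

Tensors are NHWC float32 and conv weights are (kh, kw, c_in, c_out): with
channels innermost, the im2col patch matrix is built from contiguous block
copies and every heavy operation is a single GEMM on contiguous arrays.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "conv_forward",
    "conv_backward",
    "relu_forward",
    "relu_backward",
    "maxpool_forward",
    "maxpool_backward",
    "maxunpool_forward",
    "maxunpool_backward",
    "he_init",
    "Adam",
]


def he_init(rng: np.random.Generator, c_in: int, c_out: int, kh: int, kw: int):
    """He-normal weights (kh, kw, c_in, c_out) for a ReLU conv, zero bias."""
    std = np.sqrt(2.0 / (c_in * kh * kw))
    w = rng.normal(0.0, std, size=(kh, kw, c_in, c_out)).astype(np.float32)
    b = np.zeros(c_out, dtype=np.float32)
    return w, b


def _im2col(xp: np.ndarray, h: int, wd: int, kh: int, kw: int) -> np.ndarray:
    """Patch matrix (n*h*w, kh*kw*c) from a padded NHWC input."""
    n, _, _, c = xp.shape
    cols = np.empty((n, h, wd, kh, kw, c), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, :, i, j, :] = xp[:, i : i + h, j : j + wd, :]
    return cols.reshape(n * h * wd, kh * kw * c)


def conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Same-padded cross-correlation via im2col + GEMM. Returns (out, cache)."""
    n, h, wd, c = x.shape
    kh, kw, _, k = w.shape
    ph, pw = kh // 2, kw // 2
    if ph or pw:
        xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        cols = _im2col(xp, h, wd, kh, kw)
    else:
        cols = x.reshape(n * h * wd, c)
    out = cols @ w.reshape(-1, k) + b
    return out.reshape(n, h, wd, k), (cols, x.shape, w.shape)


def conv_backward(dout: np.ndarray, w: np.ndarray, cache):
    """Gradients of a same-padded conv: (dx, dw, db)."""
    cols, x_shape, w_shape = cache
    n, h, wd, c = x_shape
    kh, kw, _, k = w_shape
    ph, pw = kh // 2, kw // 2
    dout2 = dout.reshape(-1, k)
    db = dout2.sum(axis=0)
    dw = (cols.T @ dout2).reshape(w_shape)
    dcols = (dout2 @ w.reshape(-1, k).T).reshape(n, h, wd, kh, kw, c)
    if not (ph or pw):
        return dcols.reshape(x_shape), dw, db
    dxp = np.zeros((n, h + 2 * ph, wd + 2 * pw, c), dtype=dout.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, i : i + h, j : j + wd, :] += dcols[:, :, :, i, j, :]
    return dxp[:, ph : ph + h, pw : pw + wd, :], dw, db


def relu_forward(x: np.ndarray):
    mask = x > 0
    return x * mask, mask


def relu_backward(dout: np.ndarray, mask: np.ndarray):
    return dout * mask


def _to_windows(x: np.ndarray):
    """(n, h, w, c) -> (n, h/2, w/2, c, 4) view of the 2x2 windows."""
    n, h, w, c = x.shape
    return (
        x.reshape(n, h // 2, 2, w // 2, 2, c)
        .transpose(0, 1, 3, 5, 2, 4)
        .reshape(n, h // 2, w // 2, c, 4)
    )


def _from_windows(xw: np.ndarray, h: int, w: int):
    n = xw.shape[0]
    c = xw.shape[3]
    return (
        xw.reshape(n, h // 2, w // 2, c, 2, 2)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(n, h, w, c)
    )


def maxpool_forward(x: np.ndarray):
    """2x2 stride-2 max pooling. Returns (out, switches, input_hw)."""
    n, h, w, c = x.shape
    xw = _to_windows(x)
    idx = xw.argmax(axis=-1)
    out = np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0]
    return out, idx, (h, w)


def maxpool_backward(dout: np.ndarray, idx: np.ndarray, hw):
    h, w = hw
    dxw = np.zeros(dout.shape + (4,), dtype=dout.dtype)
    np.put_along_axis(dxw, idx[..., None], dout[..., None], axis=-1)
    return _from_windows(dxw, h, w)


def maxunpool_forward(x: np.ndarray, idx: np.ndarray, hw):
    """Place each value at the switch position recorded by the matched
    pooling layer (the pooling operator's adjoint)."""
    return maxpool_backward(x, idx, hw)


def maxunpool_backward(dout: np.ndarray, idx: np.ndarray):
    dw = _to_windows(dout)
    return np.take_along_axis(dw, idx[..., None], axis=-1)[..., 0]


class Adam:
    """Adam with per-call learning rate (the schedule lives outside)."""

    def __init__(self, params: dict, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict, lr: float) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            mhat = self.m[k] / b1c
            vhat = self.v[k] / b2c
            p -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
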