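"""Minimal NumPy neural-network engine for the dose-reconstruction models.

Implements exactly the pieces the encoder–decoder estimators need — dense
layers, 2D/3D convolutions (im2col), nearest-neighbour upsampling, batch
normalization, LeakyReLU/tanh, mean-squared-error loss and Adam — with
explicit forward/backward passes. Everything is seeded through
``numpy.random.Generator``, so training is bit-reproducible on a fixed
platform.

Array layouts: dense layers take (B, D); convolutions take channel-first
(B, C, H, W) or (B, C, D, H, W).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

DTYPE = np.float32  # training runs in single precision

__all__ = [
    "Dense",
    "Conv2D",
    "Conv3D",
    "Upsample",
    "BatchNorm",
    "LeakyReLU",
    "Tanh",
    "Reshape",
    "Sequential",
    "Adam",
    "mse_loss",
]


class Layer:
    def forward(self, x, train: bool):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError

    def params(self):
        return []


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng):
        scale = np.sqrt(2.0 / d_in)
        self.W = (rng.standard_normal((d_in, d_out)) * scale).astype(DTYPE)
        self.b = np.zeros(d_out, dtype=DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.gW[...] = self._x.T @ grad
        self.gb[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]


@njit(cache=True, fastmath=True)
def _conv2d_fwd(xp, W, out, stride):
    B, C, Hp, Wp = xp.shape
    O, _, k, _ = W.shape
    _, _, Ho, Wo = out.shape
    for bb in range(B):
        for o in range(O):
            for c in range(C):
                for i in range(k):
                    for j in range(k):
                        wv = W[o, c, i, j]
                        for h in range(Ho):
                            for w in range(Wo):
                                out[bb, o, h, w] += wv * xp[bb, c, h * stride + i, w * stride + j]


@njit(cache=True, fastmath=True)
def _conv2d_bwd(xp, g, W, gW, gxp, stride):
    B, C, Hp, Wp = xp.shape
    O, _, k, _ = W.shape
    _, _, Ho, Wo = g.shape
    for bb in range(B):
        for o in range(O):
            for c in range(C):
                for i in range(k):
                    for j in range(k):
                        wv = W[o, c, i, j]
                        acc = 0.0
                        for h in range(Ho):
                            for w in range(Wo):
                                gv = g[bb, o, h, w]
                                acc += gv * xp[bb, c, h * stride + i, w * stride + j]
                                gxp[bb, c, h * stride + i, w * stride + j] += gv * wv
                        gW[o, c, i, j] += acc


@njit(cache=True, fastmath=True)
def _conv3d_fwd_s1(xp, W, out):
    B, C, Dp, Hp, Wp = xp.shape
    O, _, k, _, _ = W.shape
    _, _, Do, Ho, Wo = out.shape
    for bb in range(B):
        for o in range(O):
            for c in range(C):
                for i in range(k):
                    for j in range(k):
                        for l in range(k):
                            wv = W[o, c, i, j, l]
                            for d in range(Do):
                                for h in range(Ho):
                                    orow = out[bb, o, d, h]
                                    xrow = xp[bb, c, d + i, h + j]
                                    for w in range(Wo):
                                        orow[w] += wv * xrow[w + l]


@njit(cache=True, fastmath=True)
def _conv3d_bwd_s1(xp, g, W, gW, gxp, need_gx):
    B, C, Dp, Hp, Wp = xp.shape
    O, _, k, _, _ = W.shape
    _, _, Do, Ho, Wo = g.shape
    for bb in range(B):
        for o in range(O):
            for c in range(C):
                for i in range(k):
                    for j in range(k):
                        for l in range(k):
                            wv = W[o, c, i, j, l]
                            acc = 0.0
                            for d in range(Do):
                                for h in range(Ho):
                                    grow = g[bb, o, d, h]
                                    xrow = xp[bb, c, d + i, h + j]
                                    if need_gx:
                                        gxrow = gxp[bb, c, d + i, h + j]
                                        for w in range(Wo):
                                            gv = grow[w]
                                            acc += gv * xrow[w + l]
                                            gxrow[w + l] += gv * wv
                                    else:
                                        for w in range(Wo):
                                            acc += grow[w] * xrow[w + l]
                            gW[o, c, i, j, l] += acc


@njit(cache=True, fastmath=True)
def _conv3d_fwd(xp, W, out, stride):
    B, C, Dp, Hp, Wp = xp.shape
    O, _, k, _, _ = W.shape
    _, _, Do, Ho, Wo = out.shape
    for bb in range(B):
        for o in range(O):
            for c in range(C):
                for i in range(k):
                    for j in range(k):
                        for l in range(k):
                            wv = W[o, c, i, j, l]
                            for d in range(Do):
                                for h in range(Ho):
                                    for w in range(Wo):
                                        out[bb, o, d, h, w] += (
                                            wv
                                            * xp[bb, c, d * stride + i, h * stride + j, w * stride + l]
                                        )


@njit(cache=True, fastmath=True)
def _conv3d_bwd(xp, g, W, gW, gxp, stride):
    B, C, Dp, Hp, Wp = xp.shape
    O, _, k, _, _ = W.shape
    _, _, Do, Ho, Wo = g.shape
    for bb in range(B):
        for o in range(O):
            for c in range(C):
                for i in range(k):
                    for j in range(k):
                        for l in range(k):
                            wv = W[o, c, i, j, l]
                            acc = 0.0
                            for d in range(Do):
                                for h in range(Ho):
                                    for w in range(Wo):
                                        gv = g[bb, o, d, h, w]
                                        acc += gv * xp[
                                            bb, c, d * stride + i, h * stride + j, w * stride + l
                                        ]
                                        gxp[
                                            bb, c, d * stride + i, h * stride + j, w * stride + l
                                        ] += gv * wv
                            gW[o, c, i, j, l] += acc


def _im2col2d(xp, k, stride, out_sp):
    """Tap-by-tap patch matrix (B, C*k*k, n_out) for 2D inputs."""
    B, C = xp.shape[0], xp.shape[1]
    Ho, Wo = out_sp
    cols = np.empty((B, C, k * k, Ho * Wo), dtype=xp.dtype)
    for t, (i, j) in enumerate([(i, j) for i in range(k) for j in range(k)]):
        cols[:, :, t, :] = xp[:, :, i : i + Ho * stride : stride, j : j + Wo * stride : stride
                              ].reshape(B, C, -1)
    return cols.reshape(B, C * k * k, Ho * Wo)


class _ConvND(Layer):
    """'Same'-padded k^nd convolution (stride subsampling).

    2D convolutions run through an im2col + BLAS matmul path; 3D ones use
    compiled direct kernels (the im2col working set at 3D sizes thrashes).
    Weights are stored as (c_out, c_in, k, ...); params() exposes them to
    the optimizer.
    """

    nd: int

    def __init__(self, c_in: int, c_out: int, rng, k: int = 3, stride: int = 1):
        fan_in = c_in * k**self.nd
        self.W = (
            rng.standard_normal((c_out, c_in) + (k,) * self.nd) * np.sqrt(2.0 / fan_in)
        ).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.k, self.stride = k, stride
        self._fwd = _conv2d_fwd if self.nd == 2 else _conv3d_fwd
        self._bwd = _conv2d_bwd if self.nd == 2 else _conv3d_bwd

    def _pad(self, x):
        # replicate ("edge") padding: border outputs see the same input
        # statistics as the interior, avoiding corner artifacts that MSE is
        # too dilute to correct
        pad = (self.k - 1) // 2
        pads = [(0, 0), (0, 0)] + [(pad, pad)] * self.nd
        return np.pad(x, pads, mode="edge")

    def _fold_pad_grad(self, gxp):
        """Adjoint of replicate padding: fold border-slab gradients back."""
        pad = (self.k - 1) // 2
        if pad == 0:
            return gxp
        for ax in range(2, 2 + self.nd):
            lo0 = [slice(None)] * gxp.ndim
            lo1 = [slice(None)] * gxp.ndim
            hi0 = [slice(None)] * gxp.ndim
            hi1 = [slice(None)] * gxp.ndim
            lo0[ax], lo1[ax] = 0, 1
            hi0[ax], hi1[ax] = -1, -2
            gxp[tuple(lo1)] += gxp[tuple(lo0)]
            gxp[tuple(hi1)] += gxp[tuple(hi0)]
        sl = (slice(None), slice(None)) + tuple(slice(pad, -pad) for _ in range(self.nd))
        return gxp[sl]

    def forward(self, x, train):
        x = np.ascontiguousarray(x, dtype=DTYPE)
        pad = (self.k - 1) // 2
        out_sp = tuple(
            (x.shape[2 + i] + 2 * pad - self.k) // self.stride + 1 for i in range(self.nd)
        )
        self._xp = self._pad(x)
        self._x_shape = x.shape
        B = x.shape[0]
        if self.nd == 2:
            self._cols = _im2col2d(self._xp, self.k, self.stride, out_sp)
            Wf = self.W.reshape(self.W.shape[0], -1)
            out = (np.matmul(Wf, self._cols) + self.b[None, :, None]).reshape(
                (B, -1) + out_sp
            )
            return out
        out = np.empty((B, self.W.shape[0]) + out_sp, dtype=DTYPE)
        out[...] = self.b.reshape((1, -1) + (1,) * self.nd)
        if self.stride == 1 and self.nd == 3:
            _conv3d_fwd_s1(self._xp, self.W, out)
        else:
            self._fwd(self._xp, self.W, out, self.stride)
        return out

    def backward(self, grad):
        grad = np.ascontiguousarray(grad, dtype=DTYPE)
        pad = (self.k - 1) // 2
        self.gb[...] = grad.sum(axis=(0,) + tuple(range(2, 2 + self.nd)))
        if self.nd == 2:
            B = grad.shape[0]
            g = grad.reshape(B, grad.shape[1], -1)
            Wf = self.W.reshape(self.W.shape[0], -1)
            self.gW[...] = np.matmul(g, self._cols.transpose(0, 2, 1)).sum(axis=0).reshape(
                self.gW.shape
            )
            gcols = np.matmul(Wf.T, g).reshape(
                B, self._x_shape[1], self.k * self.k, -1
            )
            gxp = np.zeros_like(self._xp)
            Ho = (self._x_shape[2] + 2 * pad - self.k) // self.stride + 1
            Wo = (self._x_shape[3] + 2 * pad - self.k) // self.stride + 1
            for t, (i, j) in enumerate([(i, j) for i in range(self.k) for j in range(self.k)]):
                gxp[:, :, i : i + Ho * self.stride : self.stride,
                    j : j + Wo * self.stride : self.stride] += gcols[:, :, t, :].reshape(
                    B, -1, Ho, Wo
                )
            return self._fold_pad_grad(gxp)
        else:
            self.gW[...] = 0.0
            need_gx = getattr(self, "input_grad", True)
            if self.stride == 1:
                gxp = (
                    np.zeros_like(self._xp)
                    if need_gx
                    else np.zeros((1, 1, 1, 1, 1), dtype=DTYPE)
                )
                _conv3d_bwd_s1(self._xp, grad, self.W, self.gW, gxp, need_gx)
            else:
                # generic kernel always scatters into a full-size buffer
                gxp = np.zeros_like(self._xp)
                self._bwd(self._xp, grad, self.W, self.gW, gxp, self.stride)
            if not need_gx:
                return None
            return self._fold_pad_grad(gxp)

    def params(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class Conv2D(_ConvND):
    nd = 2


class Conv3D(_ConvND):
    nd = 3


class Upsample(Layer):
    """Nearest-neighbour x2 upsampling over all spatial axes."""

    def forward(self, x, train):
        self._nd = x.ndim - 2
        out = x
        for ax in range(2, 2 + self._nd):
            out = np.repeat(out, 2, axis=ax)
        return out

    def backward(self, grad):
        g = grad
        for ax in range(2, 2 + self._nd):
            sp = g.shape[ax] // 2
            shape = list(g.shape)
            shape[ax : ax + 1] = [sp, 2]
            g = g.reshape(shape).sum(axis=ax + 1)
        return g


class BatchNorm(Layer):
    """Normalization over batch and spatial axes, per channel (axis 1 for
    conv inputs, axis -1 for dense inputs)."""

    def __init__(self, n: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n, dtype=DTYPE)
        self.beta = np.zeros(n, dtype=DTYPE)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.run_mean = np.zeros(n, dtype=DTYPE)
        self.run_var = np.ones(n, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps

    def _axes(self, x):
        return (0,) if x.ndim == 2 else (0,) + tuple(range(2, x.ndim))

    def _shape(self, x):
        return (1, -1) + (1,) * (x.ndim - 2) if x.ndim > 2 else (1, -1)

    def forward(self, x, train):
        axes, sh = self._axes(x), self._shape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean.reshape(sh)) * self._inv.reshape(sh)
        self._axes_cache, self._sh = axes, sh
        return self.gamma.reshape(sh) * self._xhat + self.beta.reshape(sh)

    def backward(self, grad):
        axes, sh = self._axes_cache, self._sh
        m = np.prod([grad.shape[a] for a in axes])
        self.ggamma[...] = (grad * self._xhat).sum(axis=axes)
        self.gbeta[...] = grad.sum(axis=axes)
        gx = (
            self.gamma.reshape(sh)
            * self._inv.reshape(sh)
            / m
            * (
                m * grad
                - grad.sum(axis=axes).reshape(sh)
                - self._xhat * (grad * self._xhat).sum(axis=axes).reshape(sh)
            )
        )
        return gx

    def params(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]

    def state(self):
        return {"run_mean": self.run_mean, "run_var": self.run_var}


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def forward(self, x, train):
        self._mask = x >= 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.alpha * grad)


class Tanh(Layer):
    def forward(self, x, train):
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad):
        return grad * (1.0 - self._y**2)


class Reshape(Layer):
    def __init__(self, shape):
        self.shape = tuple(shape)

    def forward(self, x, train):
        self._in = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad):
        return grad.reshape(self._in)


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
            if grad is None:  # a data-facing layer ends the chain
                break
        return grad

    def params(self):
        return [p for l in self.layers for p in l.params()]


@njit(cache=True, fastmath=True)
def _adam_update(p, g, m, v, lr, b1, b2, b1t, b2t, eps):
    for i in range(p.size):
        gi = g[i]
        m[i] = b1 * m[i] + (1.0 - b1) * gi
        v[i] = b2 * v[i] + (1.0 - b2) * gi * gi
        p[i] -= lr * (m[i] / b1t) / (math.sqrt(v[i] / b2t) + eps)


class Adam:
    def __init__(self, params, lr: float = 2e-4, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            _adam_update(p.reshape(-1), g.reshape(-1), m.reshape(-1), v.reshape(-1),
                         self.lr, self.b1, self.b2, b1t, b2t, self.eps)


def mse_loss(pred, target):
    """Mean squared error and its gradient w.r.t. ``pred``."""
    diff = pred - target
    return float(np.mean(diff.astype(np.float64) ** 2)), (2.0 / diff.size) * diff
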