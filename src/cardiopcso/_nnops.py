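"""Low-level NumPy neural-network primitives used by the U-Net.

Convolutions are im2col + BLAS matmul; every layer provides an explicit
backward pass.  Shapes follow the (N, C, H, W) convention.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_BN_EPS = 1e-5


def conv_output_size(n: int, k: int, padding: str) -> int:
    """Spatial size after a stride-1 convolution: ``n`` for same padding,
    ``n - k + 1`` for valid (e.g. 256 -> 254 with a 3x3 kernel)."""
    if padding == "same":
        return n
    if padding == "valid":
        out = n - k + 1
        if out < 1:
            raise ValueError(f"valid convolution of size {n} with kernel {k} is empty")
        return out
    raise ValueError(f"unknown padding {padding!r}")


class Conv2d:
    """3x3 (or kxk) stride-1 convolution, He-Normal initialized."""

    def __init__(self, c_in, c_out, k=3, padding="same", rng=None):
        self.c_in, self.c_out, self.k, self.padding = c_in, c_out, k, padding
        rng = rng or np.random.default_rng()
        fan_in = c_in * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out))
        self.b = np.zeros(c_out)
        self._cache = None

    def forward(self, x, train=False):
        N, C, H, W = x.shape
        k = self.k
        if self.padding == "same":
            p = k // 2
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        else:
            xp = x
        Ho = conv_output_size(H, k, self.padding)
        Wo = conv_output_size(W, k, self.padding)
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # N,C,Ho,Wo,k,k
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * Ho * Wo, C * k * k)
        out = cols @ self.W + self.b
        self._cache = (cols, x.shape, (Ho, Wo))
        return out.reshape(N, Ho, Wo, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout):
        cols, xshape, (Ho, Wo) = self._cache
        N, C, H, W = xshape
        k = self.k
        dmat = dout.transpose(0, 2, 3, 1).reshape(N * Ho * Wo, self.c_out)
        self.dW = cols.T @ dmat
        self.db = dmat.sum(axis=0)
        dcols = (dmat @ self.W.T).reshape(N, Ho, Wo, C, k, k)
        p = k // 2 if self.padding == "same" else 0
        dxp = np.zeros((N, C, H + 2 * p, W + 2 * p))
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki : ki + Ho, kj : kj + Wo] += dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + H, p : p + W] if p else dxp

    def params(self):
        return [("W", self), ("b", self)]


class BatchNorm2d:
    def __init__(self, c, momentum=0.9):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self._cache = None

    def forward(self, x, train=False):
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train, x.shape)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dout):
        xhat, inv, train, shape = self._cache
        self.dgamma = (dout * xhat).sum(axis=(0, 2, 3))
        self.dbeta = dout.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None] * inv[None, :, None, None]
        if not train:
            return dout * g
        m = shape[0] * shape[2] * shape[3]
        dxhat = dout * self.gamma[None, :, None, None]
        term = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        )
        return term * inv[None, :, None, None]


class ReLU:
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout:
    def __init__(self, rate):
        self.rate = rate
        self._keep = None

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0:
            self._keep = None
            return x
        rng = rng or np.random.default_rng()
        self._keep = (rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._keep

    def backward(self, dout):
        return dout if self._keep is None else dout * self._keep


class MaxPool2:
    """2x2 max pooling with stride 2; gradient routed to the argmax."""

    def forward(self, x, train=False):
        N, C, H, W = x.shape
        xf = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            N, C, H // 2, W // 2, 4
        )
        self._idx = xf.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xf, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        N, C, H, W = self._shape
        dxf = np.zeros((N, C, H // 2, W // 2, 4))
        np.put_along_axis(dxf, self._idx[..., None], dout[..., None], axis=-1)
        return dxf.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            N, C, H, W
        )


class ConvTranspose2:
    """2x2 stride-2 transposed convolution (learned 2x upsampling)."""

    def __init__(self, c_in, c_out, rng=None):
        rng = rng or np.random.default_rng()
        self.W = rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_in, c_out, 2, 2))
        self.b = np.zeros(c_out)
        self._x = None

    def forward(self, x, train=False):
        self._x = x
        N, C, H, Wd = x.shape
        out6 = np.einsum("nchw,cfab->nfhawb", x, self.W)
        out = out6.reshape(N, self.W.shape[1], 2 * H, 2 * Wd)
        return out + self.b[None, :, None, None]

    def backward(self, dout):
        x = self._x
        N, C, H, Wd = x.shape
        F = self.W.shape[1]
        d6 = dout.reshape(N, F, H, 2, Wd, 2)
        self.dW = np.einsum("nchw,nfhawb->cfab", x, d6)
        self.db = dout.sum(axis=(0, 2, 3))
        return np.einsum("nfhawb,cfab->nchw", d6, self.W)


class Adam:
    """Adam over an explicit (layer, attr) parameter list."""

    def __init__(self, param_refs, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.refs = param_refs  # list of (layer, attr_name)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(getattr(l, a)) for l, a in param_refs]
        self.v = [np.zeros_like(getattr(l, a)) for l, a in param_refs]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (layer, attr) in enumerate(self.refs):
            g = getattr(layer, "d" + attr).reshape(getattr(layer, attr).shape)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            setattr(
                layer,
                attr,
                getattr(layer, attr) - self.lr * mhat / (np.sqrt(vhat) + self.eps),
            )


def softmax_channels(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
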