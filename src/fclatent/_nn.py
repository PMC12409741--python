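"""Minimal NumPy neural-network core used by the latent embedding model.

Implements exactly what the convolutional VAE needs and nothing more:
strided 2-D convolutions with *circular* padding along the azimuth (width)
axis and zero padding along the elevation (height) axis, mirror-symmetric
transposed convolutions, fully-connected layers, ReLU, and Adam.  Transposed
convolution is realized as the adjoint of the forward convolution (the same
col2im scatter used for input gradients), which makes the decoder the exact
mirror of the encoder by construction.

Gradients are hand-derived and covered by finite-difference checks in the
test suite.  Arrays are (batch, channels, height, width), float64.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2d", "ConvTranspose2d", "Linear", "relu", "relu_grad", "Adam"]


def _pad(x: np.ndarray, ph: int, pw: int) -> np.ndarray:
    """Zero-pad the height axis, circularly pad the width axis."""
    if ph:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (0, 0)))
    if pw:
        x = np.concatenate([x[..., -pw:], x, x[..., :pw]], axis=-1)
    return x


def _unpad_grad(dxp: np.ndarray, ph: int, pw: int) -> np.ndarray:
    """Adjoint of _pad: crop the zero-padded rows, fold the wrapped columns."""
    if ph:
        dxp = dxp[:, :, ph:-ph, :]
    if pw:
        w = dxp.shape[-1] - 2 * pw
        dx = dxp[..., pw:pw + w].copy()
        dx[..., w - pw:] += dxp[..., :pw]
        dx[..., :pw] += dxp[..., pw + w:]
        return dx
    return dxp.copy()


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, ph: int, pw: int):
    """Return (cols, out_shape): cols is (B*OH*OW, C*kh*kw)."""
    xp = _pad(x, ph, pw)
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    b, c, oh, ow = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * oh * ow, c * kh * kw)
    return np.ascontiguousarray(cols), (b, oh, ow)


def _col2im(dcols: np.ndarray, x_shape, kh, kw, stride, ph, pw, out_hw):
    """Adjoint of _im2col: scatter-add column gradients back to the input."""
    b, c, h, w = x_shape
    oh, ow = out_hw
    dxp = np.zeros((b, c, h + 2 * ph, w + 2 * pw))
    d = dcols.reshape(b, oh, ow, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += d[..., i, j]
    return _unpad_grad(dxp, ph, pw)


def conv_forward(x, weight, bias, stride, ph, pw):
    """y = conv(x, weight) + bias.  weight is (Cout, Cin, kh, kw)."""
    cout, cin, kh, kw = weight.shape
    cols, (b, oh, ow) = _im2col(x, kh, kw, stride, ph, pw)
    y = cols @ weight.reshape(cout, -1).T
    if bias is not None:
        y += bias
    return y.reshape(b, oh, ow, cout).transpose(0, 3, 1, 2), cols


def conv_input_grad(dy, weight, stride, ph, pw, x_shape):
    """Gradient of conv_forward w.r.t. its input (also: transposed conv)."""
    cout, cin, kh, kw = weight.shape
    b, _, oh, ow = dy.shape
    dy_mat = dy.transpose(0, 2, 3, 1).reshape(-1, cout)
    dcols = dy_mat @ weight.reshape(cout, -1)
    return _col2im(dcols, x_shape, kh, kw, stride, ph, pw, (oh, ow))


def conv_weight_grad(dy, cols, weight_shape):
    cout = weight_shape[0]
    dy_mat = dy.transpose(0, 2, 3, 1).reshape(-1, cout)
    dw = (dy_mat.T @ cols).reshape(weight_shape)
    db = dy.sum(axis=(0, 2, 3))
    return dw, db


def _he(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(scale=np.sqrt(2.0 / fan_in), size=shape)


class Conv2d:
    """Strided conv, circular padding on width, zero padding on height.

    Padding is fixed to (kernel - stride) split evenly per side, so an input
    whose size is divisible by the stride downsamples exactly by it.
    """

    def __init__(self, cin, cout, kernel, stride, rng):
        if (kernel - stride) % 2:
            raise ValueError("kernel - stride must be even for symmetric padding")
        self.stride = stride
        self.pad = (kernel - stride) // 2
        self.weight = _he(rng, (cout, cin, kernel, kernel), cin * kernel * kernel)
        self.bias = np.zeros(cout)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)
        self._cache = None

    def forward(self, x):
        y, cols = conv_forward(x, self.weight, self.bias, self.stride, self.pad, self.pad)
        self._cache = (x.shape, cols)
        return y

    def backward(self, dy):
        x_shape, cols = self._cache
        dw, db = conv_weight_grad(dy, cols, self.weight.shape)
        self.dweight += dw
        self.dbias += db
        return conv_input_grad(dy, self.weight, self.stride, self.pad, self.pad, x_shape)

    @property
    def params(self):
        return [("weight", self), ("bias", self)]


class ConvTranspose2d:
    """Exact adjoint of Conv2d: maps a (cin, h, w) map up to (cout, s*h, s*w).

    The weight is stored in forward-conv convention (cin plays the role of
    the conv's output channels), so encoder/decoder pairs share shapes.
    """

    def __init__(self, cin, cout, kernel, stride, rng):
        if (kernel - stride) % 2:
            raise ValueError("kernel - stride must be even for symmetric padding")
        self.stride = stride
        self.pad = (kernel - stride) // 2
        self.kernel = kernel
        self.cout = cout
        self.weight = _he(rng, (cin, cout, kernel, kernel), cin * kernel * kernel)
        self.bias = np.zeros(cout)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)
        self._cache = None

    def forward(self, z):
        b, _, h, w = z.shape
        out_shape = (b, self.cout, h * self.stride, w * self.stride)
        y = conv_input_grad(z, self.weight, self.stride, self.pad, self.pad, out_shape)
        self._cache = (z, out_shape)
        return y + self.bias[None, :, None, None]

    def backward(self, dy):
        z, out_shape = self._cache
        self.dbias += dy.sum(axis=(0, 2, 3))
        cols, _ = _im2col(dy, self.kernel, self.kernel, self.stride, self.pad, self.pad)
        cin = self.weight.shape[0]
        z_mat = z.transpose(0, 2, 3, 1).reshape(-1, cin)
        self.dweight += (z_mat.T @ cols).reshape(self.weight.shape)
        dz = cols @ self.weight.reshape(cin, -1).T
        b, _, h, w = z.shape
        return dz.reshape(b, h, w, cin).transpose(0, 3, 1, 2)

    @property
    def params(self):
        return [("weight", self), ("bias", self)]


class Linear:
    def __init__(self, n_in, n_out, rng):
        self.weight = _he(rng, (n_out, n_in), n_in)
        self.bias = np.zeros(n_out)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)
        self._x = None

    def forward(self, x):
        self._x = x
        return x @ self.weight.T + self.bias

    def backward(self, dy):
        self.dweight += dy.T @ self._x
        self.dbias += dy.sum(axis=0)
        return dy @ self.weight

    @property
    def params(self):
        return [("weight", self), ("bias", self)]


def relu(x):
    return np.maximum(x, 0.0)


def relu_grad(dy, x):
    return dy * (x > 0)


class Adam:
    """Standard Adam with bias correction over a list of layers."""

    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.slots = []
        for layer in layers:
            for name, owner in layer.params:
                p = getattr(owner, name)
                self.slots.append(
                    (owner, name, np.zeros_like(p), np.zeros_like(p))
                )

    def zero_grad(self):
        for owner, name, _, _ in self.slots:
            getattr(owner, "d" + name).fill(0.0)

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for owner, name, m, v in self.slots:
            g = getattr(owner, "d" + name)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p = getattr(owner, name)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
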