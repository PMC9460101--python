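"""Minimal reverse-mode layer stack on NumPy.

Implements exactly the layers the voice-classification architectures need
(sinc-parametrized and free-form 1-D front ends, small 1-D/2-D conv blocks,
batch/layer norm, leaky-ReLU, dropout, fully connected layers, softmax
cross-entropy) with hand-derived backward passes.  The sinc front end is
the interesting case: the kernel is an analytic function of its two cutoff
frequencies, and d/df [2 f sinc(2 pi f n)] = 2 cos(2 pi f n), so the
gradient w.r.t. each cutoff is a windowed cosine probe dotted with the
kernel-level gradient.

Shapes: 1-D audio paths use (batch, channels, time); fully connected
layers use (batch, features).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import fftconvolve

from .sincfilters import (
    SincFilterBank,
    init_filterbank,
    sinc_kernel_grads,
)

_EPS = 1e-5


class Parameter:
    """A learnable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self):
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray | None:  # pragma: no cover
        raise NotImplementedError


# ---------------------------------------------------------------------------
# front ends


def _corr_kernel_grad(x: np.ndarray, grad: np.ndarray) -> np.ndarray:
    """d loss / d kernel for y[b,f] = conv_valid(x[b], k[f]).

    ``x`` is (B, N), ``grad`` is (B, F, T) with T = N - L + 1; returns (F, L).
    Computed as a batched valid correlation via FFT convolution.
    """
    corr = fftconvolve(x[:, None, :], grad[..., ::-1], mode="valid", axes=-1)
    return corr[..., ::-1].sum(axis=0)


class SincConv1d(Layer):
    """Band-pass filterbank layer: 2 learnable cutoffs per channel, no bias."""

    def __init__(self, bank: SincFilterBank):
        self.bank = bank
        self.raw_low = Parameter(bank.raw_low.copy(), "sinc.raw_low")
        self.raw_band = Parameter(bank.raw_band.copy(), "sinc.raw_band")
        self._x = None

    def params(self):
        return [self.raw_low, self.raw_band]

    def _current_bank(self) -> SincFilterBank:
        b = self.bank
        return SincFilterBank(
            n_filters=b.n_filters,
            filter_len=b.filter_len,
            sample_rate=b.sample_rate,
            raw_low=self.raw_low.value.copy(),
            raw_band=self.raw_band.value.copy(),
            window=b.window,
            min_low_hz=b.min_low_hz,
            min_band_hz=b.min_band_hz,
        )

    def forward(self, x, train):
        if x.ndim == 3:  # (B, 1, N) from a generic pipeline
            x = x[:, 0, :]
        self._x = x
        self._kernels = self._current_bank().kernels()
        return fftconvolve(x[:, None, :], self._kernels[None, :, :], mode="valid", axes=-1)

    def backward(self, grad):
        dk = _corr_kernel_grad(self._x, grad)  # (F, L)
        bank = self._current_bank()
        f1, f2 = bank.cutoffs_hz()
        nyq = bank.sample_rate / 2.0
        d_raw_low = np.zeros_like(self.raw_low.value)
        d_raw_band = np.zeros_like(self.raw_band.value)
        sgn = lambda v: np.where(v >= 0.0, 1.0, -1.0)
        for i in range(bank.n_filters):
            d_lo, d_hi = sinc_kernel_grads(
                f1[i], f2[i], bank.filter_len, bank.sample_rate, bank.window
            )
            dL_f1 = float(dk[i] @ d_lo)
            dL_f2 = float(dk[i] @ d_hi)
            f1_free = f1[i] < nyq - bank.min_band_hz  # clip inactive
            f2_free = f2[i] < nyq
            if f1_free:
                d_raw_low[i] = (dL_f1 + (dL_f2 if f2_free else 0.0)) * sgn(
                    self.raw_low.value[i]
                )
            if f2_free:
                d_raw_band[i] = dL_f2 * sgn(self.raw_band.value[i])
        self.raw_low.grad += d_raw_low
        self.raw_band.grad += d_raw_band
        return None  # first layer: input gradient unused


class Conv1dFront(Layer):
    """Free-form single-input-channel convolution front end (with bias)."""

    def __init__(self, n_filters: int, kernel_len: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(kernel_len)
        self.weight = Parameter(
            rng.uniform(-scale, scale, size=(n_filters, kernel_len)), "front.weight"
        )
        self.bias = Parameter(np.zeros(n_filters), "front.bias")
        self._x = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train):
        if x.ndim == 3:
            x = x[:, 0, :]
        self._x = x
        out = fftconvolve(x[:, None, :], self.weight.value[None, :, :], mode="valid", axes=-1)
        return out + self.bias.value[None, :, None]

    def backward(self, grad):
        self.weight.grad += _corr_kernel_grad(self._x, grad)
        self.bias.grad += grad.sum(axis=(0, 2))
        return None


class SpectrogramFront(Layer):
    """Fixed log-magnitude STFT: (B, N) waveform -> (B, 1, F, T) image.

    Not learnable; sits first in the 2-D baseline so no input gradient is
    required.
    """

    def __init__(self, sample_rate: float, win_s: float = 0.025, hop_s: float = 0.010):
        self.nperseg = int(round(win_s * sample_rate))
        self.hop = int(round(hop_s * sample_rate))
        self.window = np.hanning(self.nperseg)

    def forward(self, x, train):
        frames = sliding_window_view(x, self.nperseg, axis=-1)[:, :: self.hop, :]
        spec = np.abs(np.fft.rfft(frames * self.window, axis=-1))
        img = np.log10(spec + 1e-8)
        return img.transpose(0, 2, 1)[:, None, :, :]  # (B, 1, freq, time)

    def backward(self, grad):
        return None

    def out_shape(self, n_samples: int) -> tuple[int, int]:
        n_t = (n_samples - self.nperseg) // self.hop + 1
        return self.nperseg // 2 + 1, n_t


# ---------------------------------------------------------------------------
# generic layers


class Conv1d(Layer):
    """Multi-channel valid convolution, stride 1 (small kernels)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(in_ch * kernel)
        self.weight = Parameter(
            rng.uniform(-scale, scale, size=(out_ch, in_ch, kernel)), "conv.weight"
        )
        self.bias = Parameter(np.zeros(out_ch), "conv.bias")
        self.kernel = kernel

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train):
        self._x = x
        B, C, T = x.shape
        k = self.kernel
        win = sliding_window_view(x, k, axis=2)  # (B, C, T', k)
        Tp = win.shape[2]
        col = win.transpose(0, 2, 1, 3).reshape(B * Tp, C * k)
        self._col = col
        Wm = self.weight.value.reshape(self.weight.value.shape[0], C * k)
        out = col @ Wm.T + self.bias.value
        return out.reshape(B, Tp, -1).transpose(0, 2, 1)

    def backward(self, grad):
        B, O, Tp = grad.shape
        C, k = self.weight.value.shape[1:]
        g2 = grad.transpose(0, 2, 1).reshape(B * Tp, O)
        self.weight.grad += (g2.T @ self._col).reshape(O, C, k)
        self.bias.grad += g2.sum(axis=0)
        Wm = self.weight.value.reshape(O, C * k)
        dcol = (g2 @ Wm).reshape(B, Tp, C, k).transpose(0, 2, 1, 3)  # (B, C, T', k)
        dx = np.zeros_like(self._x)
        for l in range(k):
            dx[:, :, l : l + Tp] += dcol[:, :, :, l]
        return dx


class MaxPool1d(Layer):
    def __init__(self, pool: int):
        self.pool = pool

    def forward(self, x, train):
        B, C, T = x.shape
        p = self.pool
        Tt = (T // p) * p
        self._in_T = T
        blocks = x[:, :, :Tt].reshape(B, C, Tt // p, p)
        self._arg = blocks.argmax(axis=3)
        return np.take_along_axis(blocks, self._arg[..., None], axis=3)[..., 0]

    def backward(self, grad):
        B, C, Tb = grad.shape
        p = self.pool
        dblocks = np.zeros((B, C, Tb, p))
        np.put_along_axis(dblocks, self._arg[..., None], grad[..., None], axis=3)
        dx = np.zeros((B, C, self._in_T))
        dx[:, :, : Tb * p] = dblocks.reshape(B, C, Tb * p)
        return dx


class Conv2dTiled(Layer):
    """2-D convolution with kernel == stride (non-overlapping tiles).

    Input is zero-padded on the bottom/right so every tile is full; output
    size is ceil(H/s) x ceil(W/s).  Matches the (3,3)-kernel, (3,3)-stride
    blocks of the 2-D baseline.
    """

    def __init__(self, in_ch: int, out_ch: int, size: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(in_ch * size * size)
        self.weight = Parameter(
            rng.uniform(-scale, scale, size=(out_ch, in_ch, size, size)), "conv2d.weight"
        )
        self.bias = Parameter(np.zeros(out_ch), "conv2d.bias")
        self.size = size

    def params(self):
        return [self.weight, self.bias]

    def _pad(self, x):
        s = self.size
        B, C, H, W = x.shape
        Hp, Wp = -(-H // s) * s, -(-W // s) * s
        if (Hp, Wp) != (H, W):
            x = np.pad(x, ((0, 0), (0, 0), (0, Hp - H), (0, Wp - W)))
        return x

    def forward(self, x, train):
        self._in_shape = x.shape
        s = self.size
        xp = self._pad(x)
        B, C, Hp, Wp = xp.shape
        tiles = xp.reshape(B, C, Hp // s, s, Wp // s, s).transpose(0, 2, 4, 1, 3, 5)
        self._col = tiles.reshape(B, Hp // s, Wp // s, C * s * s)
        O = self.weight.value.shape[0]
        Wm = self.weight.value.reshape(O, -1)
        out = self._col @ Wm.T + self.bias.value
        return out.transpose(0, 3, 1, 2)  # (B, O, H', W')

    def backward(self, grad):
        s = self.size
        B, O, Ho, Wo = grad.shape
        C = self.weight.value.shape[1]
        g2 = grad.transpose(0, 2, 3, 1)  # (B, H', W', O)
        self.weight.grad += np.einsum("bhwo,bhwc->oc", g2, self._col).reshape(
            O, C, s, s
        )
        self.bias.grad += g2.sum(axis=(0, 1, 2))
        Wm = self.weight.value.reshape(O, -1)
        dcol = g2 @ Wm  # (B, H', W', C*s*s)
        dxp = dcol.reshape(B, Ho, Wo, C, s, s).transpose(0, 3, 1, 4, 2, 5).reshape(
            B, C, Ho * s, Wo * s
        )
        _, _, H, W = self._in_shape
        return dxp[:, :, :H, :W]


class MaxPool2dTiled(Layer):
    """Non-overlapping 2-D max pool with bottom/right -inf padding (ceil mode)."""

    def __init__(self, size: int):
        self.size = size

    def forward(self, x, train):
        s = self.size
        self._in_shape = x.shape
        B, C, H, W = x.shape
        Hp, Wp = -(-H // s) * s, -(-W // s) * s
        xp = np.full((B, C, Hp, Wp), -np.inf)
        xp[:, :, :H, :W] = x
        tiles = xp.reshape(B, C, Hp // s, s, Wp // s, s).transpose(0, 1, 2, 4, 3, 5)
        flat = tiles.reshape(B, C, Hp // s, Wp // s, s * s)
        self._arg = flat.argmax(axis=4)
        return np.take_along_axis(flat, self._arg[..., None], axis=4)[..., 0]

    def backward(self, grad):
        s = self.size
        B, C, H, W = self._in_shape
        Ho, Wo = grad.shape[2], grad.shape[3]
        dflat = np.zeros((B, C, Ho, Wo, s * s))
        np.put_along_axis(dflat, self._arg[..., None], grad[..., None], axis=4)
        dxp = dflat.reshape(B, C, Ho, Wo, s, s).transpose(0, 1, 2, 4, 3, 5).reshape(
            B, C, Ho * s, Wo * s
        )
        return dxp[:, :, :H, :W]


class BatchNorm(Layer):
    """Per-channel batch normalization with affine and running statistics.

    Accepts (B, D), (B, C, T) or (B, C, H, W); statistics are taken over all
    axes except the channel axis (axis 1, or the feature axis for 2-D input).
    """

    def __init__(self, n_ch: int, momentum: float = 0.1):
        self.gamma = Parameter(np.ones(n_ch), "bn.gamma")
        self.beta = Parameter(np.zeros(n_ch), "bn.beta")
        self.momentum = momentum
        self.run_mean = np.zeros(n_ch)
        self.run_var = np.ones(n_ch)

    def params(self):
        return [self.gamma, self.beta]

    def _axes(self, x):
        return (0,) if x.ndim == 2 else (0,) + tuple(range(2, x.ndim))

    def _bshape(self, x):
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x, train):
        axes = self._axes(x)
        sh = self._bshape(x)
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = (1 - self.momentum) * self.run_mean + self.momentum * mu
            self.run_var = (1 - self.momentum) * self.run_var + self.momentum * var
        else:
            mu, var = self.run_mean, self.run_var
        std = np.sqrt(var + _EPS)
        self._xhat = (x - mu.reshape(sh)) / std.reshape(sh)
        self._std = std
        self._train = train
        return self.gamma.value.reshape(sh) * self._xhat + self.beta.value.reshape(sh)

    def backward(self, grad):
        axes = self._axes(grad)
        sh = self._bshape(grad)
        self.gamma.grad += (grad * self._xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        gs = self.gamma.value.reshape(sh) / self._std.reshape(sh)
        if not self._train:
            return grad * gs
        gmean = grad.mean(axis=axes).reshape(sh)
        gxmean = (grad * self._xhat).mean(axis=axes).reshape(sh)
        return gs * (grad - gmean - self._xhat * gxmean)


class LayerNorm(Layer):
    """Per-sample normalization over all non-batch dimensions (no affine)."""

    def forward(self, x, train):
        axes = tuple(range(1, x.ndim))
        mu = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        self._std = np.sqrt(var + _EPS)
        self._xhat = (x - mu) / self._std
        return self._xhat

    def backward(self, grad):
        axes = tuple(range(1, grad.ndim))
        gmean = grad.mean(axis=axes, keepdims=True)
        gxmean = (grad * self._xhat).mean(axis=axes, keepdims=True)
        return (grad - gmean - self._xhat * gxmean) / self._std


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope

    def forward(self, x, train):
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.slope * grad)


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout fraction must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x, train):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(n_in)
        self.weight = Parameter(rng.uniform(-scale, scale, size=(n_in, n_out)), "fc.weight")
        self.bias = Parameter(np.zeros(n_out), "fc.bias")

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train):
        self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, grad):
        self.weight.grad += self._x.T @ grad
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
            if grad is None:
                break
        return grad


# ---------------------------------------------------------------------------
# loss and optimizer


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_xent(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. logits."""
    p = softmax(logits)
    B = logits.shape[0]
    loss = -np.log(p[np.arange(B), labels] + 1e-12).mean()
    dlogits = p.copy()
    dlogits[np.arange(B), labels] -= 1.0
    return float(loss), dlogits / B


class Adam:
    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
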