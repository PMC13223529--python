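"""Minimal CNN building blocks on numpy with explicit forward/backward passes.

Every layer caches what its backward pass needs during ``forward`` and returns
the gradient with respect to its input from ``backward``.  Convolutions are
bias-free and batch normalization carries no learnable affine pair; the only
bias in the segmentation models lives in the final 1x1 classifier.  This
convention is load-bearing: the published parameter budget of the network is a
weights-only count, and the empirical counter in :mod:`feunet.param_math`
enumerates exactly the arrays registered here.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "BilinearUpsample",
    "Adam",
    "kaiming_normal",
]


class Parameter:
    """A trainable array together with its accumulated gradient."""

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return int(self.value.size)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def kaiming_normal(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    """He-style initialization for ReLU networks."""
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Module:
    """Base class: tracks children and parameters, toggles train/eval mode."""

    def __init__(self) -> None:
        self.training = True
        self._children: list[Module] = []
        self._params: list[Parameter] = []

    def add(self, child: "Module") -> "Module":
        self._children.append(child)
        return child

    def register(self, param: Parameter) -> Parameter:
        self._params.append(param)
        return param

    def parameters(self) -> list[Parameter]:
        out = list(self._params)
        for c in self._children:
            out.extend(c.parameters())
        return out

    def set_training(self, mode: bool) -> None:
        self.training = mode
        for c in self._children:
            c.set_training(mode)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def num_params(self) -> int:
        return sum(p.size for p in self.parameters())


class Conv2d(Module):
    """2D convolution via im2col.  ``padding`` defaults to "same" for stride 1."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        stride: int = 1,
        padding: int | None = None,
        bias: bool = False,
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ) -> None:
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError(f"kernel size must be odd, got {kernel}")
        self.in_ch, self.out_ch, self.k, self.stride = in_ch, out_ch, kernel, stride
        self.pad = (kernel // 2) if padding is None else padding
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        self.weight = self.register(
            Parameter(kaiming_normal(rng, (out_ch, in_ch, kernel, kernel), fan_in), f"{name}.weight")
        )
        self.bias = self.register(Parameter(np.zeros(out_ch), f"{name}.bias")) if bias else None
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {c}")
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        # [n, c, ho, wo, k, k] -> [n, ho*wo, c*k*k]
        col = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n, ho * wo, c * k * k)
        w2 = self.weight.value.reshape(self.out_ch, -1)
        out = col @ w2.T
        if self.bias is not None:
            out += self.bias.value
        self._cache = (col, x.shape, (ho, wo))
        return np.ascontiguousarray(out.transpose(0, 2, 1)).reshape(n, self.out_ch, ho, wo)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        col, xshape, (ho, wo) = self._cache
        n, c, h, w = xshape
        k, s, p = self.k, self.stride, self.pad
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(n, ho * wo, self.out_ch)
        dy2 = dyf.reshape(-1, self.out_ch)
        self.weight.grad += (dy2.T @ col.reshape(-1, col.shape[-1])).reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += dy2.sum(axis=0)
        dcol = (dyf @ self.weight.value.reshape(self.out_ch, -1)).reshape(n, ho, wo, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dcol.dtype)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s] += dcol[:, :, :, :, ki, kj].transpose(
                    0, 3, 1, 2
                )
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class BatchNorm2d(Module):
    """Batch normalization without a learnable affine pair (zero parameters)."""

    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        super().__init__()
        self.ch, self.eps, self.momentum = ch, eps, momentum
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * invstd[None, :, None, None]
        self._cache = (xhat, invstd, x.shape)
        return xhat

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd, (n, c, h, w) = self._cache
        if not self.training:
            return dy * invstd[None, :, None, None]
        m = n * h * w
        s1 = dy.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dy * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (invstd[None, :, None, None] / m) * (m * dy - s1 - xhat * s2)


class ReLU(Module):
    def __init__(self) -> None:
        super().__init__()
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class MaxPool2d(Module):
    """Non-overlapping max pooling with a square window."""

    def __init__(self, window: int) -> None:
        super().__init__()
        self.window = window
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        m = self.window
        n, c, h, w = x.shape
        if h % m or w % m:
            raise ValueError(f"spatial size {h}x{w} not divisible by pool window {m}")
        if h // m < 1 or w // m < 1:
            raise ValueError("pooling would reduce the map below one pixel")
        r = x.reshape(n, c, h // m, m, w // m, m).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // m, w // m, m * m
        )
        idx = r.argmax(axis=-1)
        self._cache = (idx, x.shape)
        return np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, (n, c, h, w) = self._cache
        m = self.window
        dr = np.zeros((n, c, h // m, w // m, m * m), dtype=dy.dtype)
        np.put_along_axis(dr, idx[..., None], dy[..., None], axis=-1)
        return dr.reshape(n, c, h // m, w // m, m, m).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic bilinear interpolation matrix, half-pixel-centre convention."""
    mat = np.zeros((n_out, n_in), dtype=np.float32)
    scale = n_in / n_out
    for o in range(n_out):
        src = (o + 0.5) * scale - 0.5
        i0 = int(np.floor(src))
        frac = src - i0
        a = min(max(i0, 0), n_in - 1)
        b = min(max(i0 + 1, 0), n_in - 1)
        mat[o, a] += 1.0 - frac
        mat[o, b] += frac
    return mat


class BilinearUpsample(Module):
    """Upsampling by an integer factor via separable bilinear interpolation."""

    def __init__(self, factor: int) -> None:
        super().__init__()
        self.factor = factor
        self._mats: dict[int, np.ndarray] = {}
        self._cache = None

    def _mat(self, n_in: int) -> np.ndarray:
        if n_in not in self._mats:
            self._mats[n_in] = _interp_matrix(n_in * self.factor, n_in)
        return self._mats[n_in]

    def forward(self, x: np.ndarray) -> np.ndarray:
        _, _, h, w = x.shape
        mh, mw = self._mat(h), self._mat(w)
        self._cache = (mh, mw)
        return np.einsum("oh,nchw,pw->ncop", mh, x, mw, optimize=True)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mh, mw = self._cache
        return np.einsum("oh,ncop,pw->nchw", mh, dy, mw, optimize=True)


class Adam(Module):
    """Adam with coupled L2 weight decay (decay added to the raw gradient)."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-4,
        weight_decay: float = 0.0,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        super().__init__()
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
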