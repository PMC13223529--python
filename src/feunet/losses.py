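"""Nine segmentation losses and their weighted combinations.

All losses take raw class scores (logits) ``y_pred`` of shape
``[N_b, C, H, W]`` and integer labels ``[N_b, H, W]`` (or a one-hot tensor of
the same shape as the scores).  Softmax is applied internally where a loss is
defined on class probabilities; the two binary cross-entropy variants follow
their usual conventions (BCE on probabilities — here the softmax output —
and BCL on raw scores through a sigmoid).  Every loss returns a non-negative
scalar and an analytic gradient with respect to the logits, verified against
finite differences in the test-suite.

Reductions: pixel-wise losses (CE, FL, KL) average over batch and pixels;
element-wise losses (L2, BCE, BCL) also average over classes; overlap losses
(DL, TL) pool numerator/denominator over the whole batch per class and
average over classes; SF computes a soft F1 per sample and class before
averaging.  Overlap losses use a smoothing constant of 1e-6; the KL target is
an epsilon-smoothed one-hot (1e-8).

The DFK combination is the unweighted sum of Dice, focal and KL-divergence
losses.
"""

from __future__ import annotations

import numpy as np

from .config import LossSpec

__all__ = [
    "LOSS_NAMES",
    "compute_loss",
    "loss_and_grad",
    "combine",
    "combine_and_grad",
    "dfk_spec",
    "binary_cross_entropy",
]

LOSS_NAMES = ("CE", "L2", "SF", "BCE", "BCL", "DL", "TL", "FL", "KL")

_SMOOTH = 1e-6     # Dice/Tversky/soft-F1 smoothing
_KL_EPS = 1e-8     # one-hot smoothing for the KL target
_CLIP = 1e-7       # probability floor inside logarithms


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _onehot(y_true: np.ndarray, like: np.ndarray) -> np.ndarray:
    """Accept integer labels [N,H,W] or a one-hot [N,C,H,W]; return one-hot."""
    if y_true.shape == like.shape:
        return y_true.astype(like.dtype, copy=False)
    if y_true.shape != (like.shape[0],) + like.shape[2:]:
        raise ValueError(
            f"label shape {y_true.shape} does not match prediction shape {like.shape}"
        )
    C = like.shape[1]
    if y_true.min() < 0 or y_true.max() >= C:
        raise ValueError(f"label values must lie in 0..{C - 1}")
    oh = np.zeros_like(like)
    np.put_along_axis(oh, y_true[:, None].astype(np.int64), 1.0, axis=1)
    return oh


def _chain_softmax(p: np.ndarray, dp: np.ndarray) -> np.ndarray:
    """Jacobian-vector product of softmax: dz = p * (dp - <dp, p>)."""
    return p * (dp - (dp * p).sum(axis=1, keepdims=True))


def _class_axis_mean(per_class: np.ndarray, include_background: bool) -> tuple[np.ndarray, np.ndarray]:
    """Mean over classes with an optional background (class 0) exclusion mask."""
    C = per_class.shape[-1]
    mask = np.ones(C, dtype=np.float32)
    if not include_background and C > 1:
        mask[0] = 0.0
    return (per_class * mask).sum(-1) / mask.sum(), mask


def binary_cross_entropy(probs: np.ndarray, targets: np.ndarray) -> float:
    """Elementwise binary cross-entropy on probabilities; validates the range."""
    if probs.shape != targets.shape:
        raise ValueError(f"probs shape {probs.shape} != targets shape {targets.shape}")
    if probs.min() <= 0.0 or probs.max() >= 1.0:
        bad = float(probs.min()) if probs.min() <= 0 else float(probs.max())
        raise ValueError(f"BCE requires probabilities strictly inside (0, 1); got {bad}")
    return float(-np.mean(targets * np.log(probs) + (1 - targets) * np.log(1 - probs)))


def loss_and_grad(
    name: str, y_pred: np.ndarray, y_true: np.ndarray, spec: LossSpec | None = None
) -> tuple[float, np.ndarray]:
    """Scalar loss and its gradient with respect to the logits ``y_pred``."""
    spec = (spec or LossSpec()).validate()
    if name not in LOSS_NAMES:
        raise ValueError(f"unknown loss {name!r}; valid names: {', '.join(LOSS_NAMES)}")
    z = np.asarray(y_pred)
    if z.dtype != np.float64:
        z = z.astype(np.float32)
    if z.ndim != 4:
        raise ValueError(f"y_pred must be [batch, classes, H, W], got shape {z.shape}")
    y = _onehot(np.asarray(y_true), z)
    nb, C, h, w = z.shape
    npix = nb * h * w

    if name == "BCL":  # sigmoid on raw scores; no softmax involved
        s = 1.0 / (1.0 + np.exp(-z))
        val = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
        return val, (s - y) / z.size

    p = _softmax(z)
    pc = np.clip(p, _CLIP, 1.0 - _CLIP)

    if name == "CE":
        val = float(-(y * np.log(pc)).sum() / npix)
        return val, (p - y) / npix
    if name == "FL":
        lam, gam = spec.lam, spec.gamma
        one_m = 1.0 - pc
        val = float(-(lam * y * one_m**gam * np.log(pc)).sum() / npix)
        dp = -(lam * y * (-gam * one_m ** max(gam - 1.0, 0.0) * np.log(pc) * (gam > 0) + one_m**gam / pc)) / npix
        return val, _chain_softmax(p, dp)
    if name == "KL":
        yt = y * (1.0 - C * _KL_EPS) + _KL_EPS
        val = float((yt * (np.log(yt) - np.log(pc))).sum() / npix)
        return val, _chain_softmax(p, -(yt / pc) / npix)
    if name == "L2":
        val = float(((p - y) ** 2).mean())
        return val, _chain_softmax(p, 2.0 * (p - y) / z.size)
    if name == "BCE":
        val = float(-np.mean(y * np.log(pc) + (1 - y) * np.log(1 - pc)))
        dp = (-(y / pc) + (1 - y) / (1 - pc)) / z.size
        return val, _chain_softmax(p, dp)

    # overlap losses: DL, TL, SF
    if name in ("DL", "TL"):
        axes = (0, 2, 3)  # pool over batch and pixels, per class
        tp = (p * y).sum(axis=axes)
        if name == "DL":
            num = 2.0 * tp + _SMOOTH
            den = p.sum(axis=axes) + y.sum(axis=axes) + _SMOOTH
            score = num / den
            dscore_dp = (2.0 * y * den[None, :, None, None] - num[None, :, None, None]) / (
                den[None, :, None, None] ** 2
            )
        else:
            a, b = spec.alpha, spec.beta
            fp = (p * (1 - y)).sum(axis=axes)
            fn = ((1 - p) * y).sum(axis=axes)
            num = tp + _SMOOTH
            den = tp + a * fp + b * fn + _SMOOTH
            dden_dp = y + a * (1 - y) - b * y
            score = num / den
            dscore_dp = (y * den[None, :, None, None] - num[None, :, None, None] * dden_dp) / (
                den[None, :, None, None] ** 2
            )
        mean_score, mask = _class_axis_mean(score, spec.include_background)
        val = float(1.0 - mean_score)
        dp = -dscore_dp * mask[None, :, None, None] / mask.sum()
        return val, _chain_softmax(p, dp)

    if name == "SF":  # soft F1 per sample and class
        axes = (2, 3)
        num = 2.0 * (p * y).sum(axis=axes) + _SMOOTH           # [N, C]
        den = p.sum(axes) + y.sum(axes) + _SMOOTH
        score = num / den
        mean_per_sample, mask = _class_axis_mean(score, spec.include_background)
        val = float(1.0 - mean_per_sample.mean())
        dscore = (2.0 * y * den[:, :, None, None] - num[:, :, None, None]) / den[:, :, None, None] ** 2
        dp = -dscore * mask[None, :, None, None] / (mask.sum() * nb)
        return val, _chain_softmax(p, dp)

    raise AssertionError(name)


def compute_loss(
    name: str, y_pred: np.ndarray, y_true: np.ndarray, spec: LossSpec | None = None
) -> float:
    """Scalar value of a single named loss (see module docstring)."""
    return loss_and_grad(name, y_pred, y_true, spec)[0]


def combine_and_grad(
    spec: LossSpec, y_pred: np.ndarray, y_true: np.ndarray
) -> tuple[float, np.ndarray]:
    """Weighted sum of the component losses and its gradient."""
    spec.validate()
    total, grad = 0.0, None
    for name, wgt in zip(spec.components, spec.weights):
        v, g = loss_and_grad(name, y_pred, y_true, spec)
        total += wgt * v
        grad = wgt * g if grad is None else grad + wgt * g
    return total, grad


def combine(spec: LossSpec, y_pred: np.ndarray, y_true: np.ndarray) -> float:
    return combine_and_grad(spec, y_pred, y_true)[0]


def dfk_spec(**overrides) -> LossSpec:
    """The Dice + focal + KL-divergence combination, unweighted."""
    kw = dict(components=["DL", "FL", "KL"], weights=[1.0, 1.0, 1.0])
    kw.update(overrides)
    return LossSpec(**kw).validate()
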