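"""Controlled degradation of images and labels for robustness studies.

Two injectors mirror the robustness ladders studied for the liver task:
additive zero-mean Gaussian noise of variance ``v_r`` on [0,1]-scaled images
(clipped back to [0,1]), and salt-and-pepper impulse noise on binary labels,
where the "variance" ``v_s`` is the corrupted-pixel fraction, split half salt
(set to 1) and half pepper (set to 0).  Both are deterministic under the
``NoiseSpec`` seed.  The canonical variance ladder used in the robustness studies is
``NOISE_LADDER``.
"""

from __future__ import annotations

import copy

import numpy as np

from .config import NoiseSpec

__all__ = [
    "NOISE_LADDER",
    "add_gaussian_image_noise",
    "add_saltpepper_label_noise",
    "build_noisy_dataset",
]

NOISE_LADDER = (0.01, 0.02, 0.04, 0.06, 0.08, 0.1, 0.2, 0.4, 0.6, 0.8)


def add_gaussian_image_noise(image: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Add zero-mean Gaussian noise of variance ``spec.variance``, then clip to [0,1]."""
    spec.validate()
    if spec.kind != "gaussian_image":
        raise ValueError(f"expected kind 'gaussian_image', got {spec.kind!r}")
    image = np.asarray(image, dtype=np.float32)
    if image.min() < 0.0 or image.max() > 1.0:
        raise ValueError(
            "image values fall outside [0, 1]; normalize intensities before adding noise"
        )
    if spec.variance == 0.0:
        return image.copy()
    rng = np.random.default_rng(spec.seed)
    noisy = image + rng.normal(0.0, np.sqrt(spec.variance), size=image.shape)
    return np.clip(noisy, 0.0, 1.0).astype(np.float32)


def add_saltpepper_label_noise(label: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Overwrite a fraction ``v_s`` of pixels: half to 1 (salt), half to 0 (pepper).

    Positions are drawn uniformly without replacement; exactly
    ``round(v_s * label.size)`` pixels are overwritten.
    """
    spec.validate()
    if spec.kind != "saltpepper_label":
        raise ValueError(f"expected kind 'saltpepper_label', got {spec.kind!r}")
    label = np.asarray(label)
    values = set(np.unique(label).astype(int).tolist())
    if not values <= {0, 1}:
        raise ValueError(f"label must be binary, found values {sorted(values)}")
    out = label.copy()
    k = int(round(spec.variance * label.size))
    if k == 0:
        return out
    rng = np.random.default_rng(spec.seed)
    pos = rng.choice(label.size, size=k, replace=False)
    flat = out.reshape(-1)
    flat[pos[: k // 2 + k % 2]] = 1  # salt
    flat[pos[k // 2 + k % 2 :]] = 0  # pepper
    return out


def build_noisy_dataset(dataset: list, spec: NoiseSpec) -> list:
    """Return a degraded copy of a list of samples; the originals are untouched.

    Gaussian noise touches images only; salt-and-pepper touches labels only.
    Per-sample seeds are derived from ``spec.seed`` so samples are corrupted
    independently yet reproducibly.  Evaluation against clean labels is the
    caller's responsibility: degrade the *training* split only.
    """
    spec.validate()
    out = []
    for idx, sample in enumerate(dataset):
        s = copy.deepcopy(sample)
        sub = NoiseSpec(kind=spec.kind, variance=spec.variance, seed=(spec.seed * 100003 + idx) % 2**31)
        if spec.kind == "gaussian_image":
            s.image = add_gaussian_image_noise(s.image, sub)
        else:
            s.label = add_saltpepper_label_noise(s.label, sub)
        out.append(s)
    return out
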