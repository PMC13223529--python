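"""Seeded synthetic phantoms emulating the two segmentation tasks.

The generators produce data with the same tensor layout as the real studies:

* ``liver_binary`` — one smooth bright blob (an elliptical-harmonic boundary)
  on a darker textured background, 3 image channels, binary label; stands in
  for a contrast-enhanced abdominal CT slice with a liver mask.
* ``brats_multiclass`` — a brain-like elliptical foreground containing three
  concentric tumor compartments (ET core inside NET inside ED), rendered in 4
  pseudo-modalities with modality-specific contrast, 3 channels each (12 in
  total), and a 4-class label whose region mapping is nested by construction.

Also included are the preprocessing helpers used on the real volumes: picking
the most prominent slices of a volume by foreground size, dropping
multi-class slices with fewer than 20 enhancing-tumor pixels, and the seeded
90/10 train/validation split.

The phantoms are deliberately easy: intensity contrast alone nearly separates
the classes, so a small network learns them quickly on a CPU.  They make no
attempt to mimic CT Hounsfield statistics or MRI bias fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import ConfigurationError, SyntheticConfig
from .metrics_regions import TumorClass

__all__ = [
    "SegmentationSample",
    "generate_liver_like",
    "generate_brats_like",
    "generate_liver_volume",
    "select_prominent_slices",
    "filter_et_slices",
    "split_dataset",
]


@dataclass
class SegmentationSample:
    """One training sample: image stack [C,H,W] in [0,1], integer label [H,W]."""

    image: np.ndarray
    label: np.ndarray
    meta: dict = field(default_factory=dict)


def _harmonic_blob_mask(
    size: int, center: tuple[float, float], r0: float, rng: np.random.Generator, roughness: float = 0.12
) -> np.ndarray:
    """Mask of a blob whose boundary radius varies with low-order harmonics."""
    amps = [rng.uniform(-roughness, roughness) / k for k in range(2, 5)]
    phases = rng.uniform(0, 2 * np.pi, size=3)
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - center[0], xx - center[1]
    theta = np.arctan2(dy, dx)
    radius = r0 * (1.0 + sum(a * np.cos(k * theta + p) for a, k, p in zip(amps, range(2, 5), phases)))
    return (dy * dy + dx * dx) <= radius * radius


def _fit_fraction_blob(size, rng, lo, hi):
    """Draw a blob whose foreground fraction lands inside (lo, hi)."""
    target = rng.uniform(lo, hi)
    center = (rng.uniform(0.38, 0.62) * size, rng.uniform(0.38, 0.62) * size)
    r0 = size * np.sqrt(target / np.pi)
    shape_rng = np.random.default_rng(rng.integers(2**31))
    for _ in range(60):
        state = shape_rng.bit_generator.state
        mask = _harmonic_blob_mask(size, center, r0, shape_rng)
        frac = mask.mean()
        if lo < frac < hi:
            return mask
        shape_rng.bit_generator.state = state  # same shape, rescaled radius
        r0 *= np.sqrt(target / max(frac, 1e-6))
    raise ConfigurationError(
        f"could not realize a blob with foreground fraction in ({lo}, {hi}) at size {size}"
    )


def _texture(size: int, rng: np.random.Generator, sigma: float = 1.5, amp: float = 0.05) -> np.ndarray:
    return amp * ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma)


def generate_liver_like(cfg: SyntheticConfig) -> list[SegmentationSample]:
    """Binary blob-on-background slices: 3 channels, classes {0, 1}."""
    cfg.validate()
    if cfg.task != "liver_binary":
        raise ConfigurationError(f"expected task 'liver_binary', got {cfg.task!r}")
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.foreground_fraction_range
    samples = []
    for idx in range(cfg.n_samples):
        mask = _fit_fraction_blob(cfg.size, rng, lo, hi)
        soft = ndimage.gaussian_filter(mask.astype(np.float32), 0.8)
        base = 0.30 + _texture(cfg.size, rng) + 0.42 * soft
        chans = [np.clip(base + _texture(cfg.size, rng, sigma=1.0, amp=0.03), 0, 1) for _ in range(3)]
        samples.append(
            SegmentationSample(
                image=np.stack(chans).astype(np.float32),
                label=mask.astype(np.int64),
                meta={"task": "liver_binary", "classes": ["background", "organ"], "index": idx},
            )
        )
    return samples


#: per-modality additive contrast for (ET, ED, NET) on top of the brain base
_MODALITY_CONTRAST = {
    "flair": (0.10, 0.35, 0.15),
    "t1": (-0.08, -0.12, -0.10),
    "t1ce": (0.40, 0.05, 0.10),
    "t2": (0.15, 0.25, 0.08),
}


def generate_brats_like(cfg: SyntheticConfig) -> list[SegmentationSample]:
    """Nested 4-class tumor phantoms: 12 channels, classes {0, 1, 2, 3}."""
    cfg.validate()
    if cfg.task != "brats_multiclass":
        raise ConfigurationError(f"expected task 'brats_multiclass', got {cfg.task!r}")
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.foreground_fraction_range
    size = cfg.size
    yy, xx = np.mgrid[0:size, 0:size]
    samples = []
    for idx in range(cfg.n_samples):
        cy, cx = rng.uniform(0.46, 0.54, 2) * size
        ry, rx = rng.uniform(0.40, 0.46, 2) * size
        brain = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        # whole-tumor fraction drives the concentric radii
        target = rng.uniform(lo, hi)
        r_ed = size * np.sqrt(target / np.pi)
        tc_y = cy + rng.uniform(-0.10, 0.10) * size
        tc_x = cx + rng.uniform(-0.10, 0.10) * size
        shape_rng = np.random.default_rng(rng.integers(2**31))
        ed = _harmonic_blob_mask(size, (tc_y, tc_x), r_ed, shape_rng, roughness=0.10) & brain
        net = _harmonic_blob_mask(size, (tc_y, tc_x), 0.70 * r_ed, shape_rng, roughness=0.08) & ed
        et = _harmonic_blob_mask(size, (tc_y, tc_x), 0.45 * r_ed, shape_rng, roughness=0.06) & net
        label = np.zeros((size, size), dtype=np.int64)
        label[ed] = TumorClass.ED
        label[net] = TumorClass.NET
        label[et] = TumorClass.ET
        chans = []
        for mod, (c_et, c_ed, c_net) in _MODALITY_CONTRAST.items():
            soft = lambda m: ndimage.gaussian_filter(m.astype(np.float32), 0.8)
            base = 0.12 + 0.33 * soft(brain) + c_ed * soft(ed & ~net) + c_net * soft(net & ~et) + c_et * soft(et)
            base = base + _texture(size, rng)
            for _ in range(3):
                chans.append(np.clip(base + _texture(size, rng, sigma=1.0, amp=0.02), 0, 1))
        samples.append(
            SegmentationSample(
                image=np.stack(chans).astype(np.float32),
                label=label,
                meta={
                    "task": "brats_multiclass",
                    "classes": ["background", "ET", "ED", "NET"],
                    "modalities": list(_MODALITY_CONTRAST),
                    "index": idx,
                },
            )
        )
    return samples


def generate_liver_volume(
    cfg: SyntheticConfig, depth: int = 12
) -> tuple[np.ndarray, np.ndarray]:
    """A toy 'CT volume': a stack of correlated slices whose organ waxes and wanes.

    Returns (images [D,3,H,W], labels [D,H,W]); the first and last slices are
    organ-free, emulating volume ends.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.foreground_fraction_range
    center = (rng.uniform(0.42, 0.58) * cfg.size, rng.uniform(0.42, 0.58) * cfg.size)
    r_max = cfg.size * np.sqrt(hi / np.pi) * 0.95
    images, labels = [], []
    shape_seed = rng.integers(2**31)
    for d in range(depth):
        # organ cross-section follows a half-sine through the stack
        scale = np.sin(np.pi * d / (depth - 1)) if depth > 1 else 1.0
        r0 = r_max * scale
        if r0 < 1.5:
            mask = np.zeros((cfg.size, cfg.size), dtype=bool)
        else:
            mask = _harmonic_blob_mask(cfg.size, center, r0, np.random.default_rng(shape_seed))
        soft = ndimage.gaussian_filter(mask.astype(np.float32), 0.8)
        base = 0.30 + _texture(cfg.size, rng) + 0.42 * soft
        img = np.stack(
            [np.clip(base + _texture(cfg.size, rng, sigma=1.0, amp=0.03), 0, 1) for _ in range(3)]
        )
        images.append(img.astype(np.float32))
        labels.append(mask.astype(np.int64))
    return np.stack(images), np.stack(labels)


def select_prominent_slices(volume_labels: np.ndarray, k: int) -> list[int]:
    """Indices of the ``k`` slices with the largest foreground pixel counts.

    Ties break toward the lower index; all-empty slices are never selected, so
    fewer than ``k`` indices may be returned.
    """
    volume_labels = np.asarray(volume_labels)
    if volume_labels.ndim != 3 or volume_labels.shape[0] == 0:
        raise ValueError("volume_labels must be a non-empty stack [D, H, W]")
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = (volume_labels > 0).sum(axis=(1, 2))
    order = sorted(range(len(counts)), key=lambda i: (-counts[i], i))
    return [i for i in order[:k] if counts[i] > 0]


def filter_et_slices(dataset: list[SegmentationSample], min_et: int = 20) -> list[SegmentationSample]:
    """Keep multi-class samples with at least ``min_et`` enhancing-tumor pixels."""
    return [s for s in dataset if int((s.label == TumorClass.ET).sum()) >= min_et]


def split_dataset(
    dataset: list[SegmentationSample], fraction: float, seed: int
) -> tuple[list[SegmentationSample], list[SegmentationSample]]:
    """Seeded shuffle, then a ``fraction`` / ``1 - fraction`` train/validation split."""
    if not (0 < fraction < 1):
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    idx = np.random.default_rng(seed).permutation(len(dataset))
    n_train = int(round(fraction * len(dataset)))
    train = [dataset[i] for i in idx[:n_train]]
    val = [dataset[i] for i in idx[n_train:]]
    return train, val
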