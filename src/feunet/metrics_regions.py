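"""Dice evaluation and the nested brain-tumor sub-region mapping.

Multi-class glioma labels use four classes — background (0), enhancing tumor
ET (1), peritumoral edema ED (2) and non-enhancing tumor NET (3) — which map
onto three nested evaluation regions:

    whole tumor   WT = ET u ED u NET
    tumor core    TC = ET u NET
    enhancing     ET

so that ET is a subset of TC is a subset of WT pixelwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

__all__ = ["TumorClass", "RegionSet", "dice_coefficient", "map_nested_regions", "evaluate_brats"]


class TumorClass(IntEnum):
    BACKGROUND = 0
    ET = 1
    ED = 2
    NET = 3


@dataclass
class RegionSet:
    """Binary masks for the three nested sub-regions of one label map."""

    wt: np.ndarray
    tc: np.ndarray
    et: np.ndarray

    def nested(self) -> bool:
        return bool(np.all(self.et <= self.tc) and np.all(self.tc <= self.wt))


def dice_coefficient(pred: np.ndarray, true: np.ndarray) -> float:
    """2|A n B| / (|A| + |B|); defined as 1.0 when both masks are empty."""
    pred = np.asarray(pred).astype(bool)
    true = np.asarray(true).astype(bool)
    if pred.shape != true.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {true.shape}")
    denom = pred.sum() + true.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(pred, true).sum() / denom)


def map_nested_regions(label: np.ndarray) -> RegionSet:
    """Map a 4-class label map onto the nested WT / TC / ET region masks."""
    label = np.asarray(label)
    valid = {int(c) for c in TumorClass}
    present = set(np.unique(label).astype(int).tolist())
    if not present <= valid:
        raise ValueError(f"unknown label values {sorted(present - valid)}; expected subset of {sorted(valid)}")
    et = label == TumorClass.ET
    tc = et | (label == TumorClass.NET)
    wt = tc | (label == TumorClass.ED)
    return RegionSet(wt=wt, tc=tc, et=et)


def evaluate_brats(
    pred_labels: np.ndarray, true_labels: np.ndarray
) -> tuple[float, float, float, float]:
    """Per-region Dice averaged over samples; mean is the average of the three regions.

    Accepts [H, W] single maps or [n, H, W] batches.
    """
    pred_labels = np.asarray(pred_labels)
    true_labels = np.asarray(true_labels)
    if pred_labels.shape != true_labels.shape:
        raise ValueError(f"prediction shape {pred_labels.shape} != label shape {true_labels.shape}")
    if pred_labels.ndim == 2:
        pred_labels, true_labels = pred_labels[None], true_labels[None]
    scores = {"wt": [], "tc": [], "et": []}
    for p, t in zip(pred_labels, true_labels):
        rp, rt = map_nested_regions(p), map_nested_regions(t)
        for key in scores:
            scores[key].append(dice_coefficient(getattr(rp, key), getattr(rt, key)))
    wt, tc, et = (float(np.mean(scores[k])) for k in ("wt", "tc", "et"))
    return (wt + tc + et) / 3.0, wt, tc, et
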