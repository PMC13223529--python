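"""Training loop, plateau learning-rate schedule, and dataset input/output.

Optimization follows the published recipe for this architecture: Adam with a
learning rate of 1e-4 and (coupled L2) weight decay of 2e-3, small batches,
and a reduce-on-plateau schedule that multiplies the learning rate by 0.1
after 20 validation epochs without improvement.  Improvement is measured on
the validation loss by default (switchable to Dice); the best-Dice parameter
state is checkpointed.  There is no early stopping beyond the schedule —
training always runs to ``max_epochs``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .architecture import FullEncoderUNet, make_optimizer
from .config import TrainConfig
from .losses import combine_and_grad
from .metrics_regions import dice_coefficient
from .synthetic_data import SegmentationSample

__all__ = [
    "TrainHistory",
    "PlateauScheduler",
    "lr_schedule_step",
    "train",
    "evaluate",
    "read_dataset",
    "write_dataset",
]


@dataclass
class TrainHistory:
    """Per-epoch records plus a pointer to (and copy of) the best-Dice state."""

    records: list = field(default_factory=list)
    best_epoch: int = 0
    best_dice: float = -1.0
    best_state: list | None = None

    def lr_trace(self) -> list[float]:
        return [r["lr"] for r in self.records]

    def to_tsv(self) -> str:
        cols = ["epoch", "train_loss", "val_loss", "val_dice", "lr"]
        lines = ["\t".join(cols)]
        for r in self.records:
            lines.append("\t".join(f"{r[c]:.6g}" if c != "epoch" else str(r[c]) for c in cols))
        return "\n".join(lines)


class PlateauScheduler:
    """Reduce-on-plateau: decay the rate after ``patience`` stalled epochs."""

    def __init__(self, lr: float, patience: int, factor: float, mode: str = "min") -> None:
        self.lr, self.patience, self.factor = lr, patience, factor
        self.sign = 1.0 if mode == "min" else -1.0
        self.best = np.inf
        self.stall = 0

    def step(self, metric: float) -> float:
        """Consume one epoch's monitored value; return the rate for the next epoch."""
        if self.sign * metric < self.best:
            self.best = self.sign * metric
            self.stall = 0
        else:
            self.stall += 1
            if self.stall >= self.patience:
                self.lr *= self.factor
                self.stall = 0
        return self.lr


def lr_schedule_step(history: TrainHistory, cfg: TrainConfig) -> float:
    """Learning rate implied by a history: replay the plateau rule over it.

    The monitored series is ``cfg.monitor`` ("val_loss", minimized, or
    "val_dice", maximized).
    """
    if not history.records:
        raise ValueError("history is empty")
    mode = "min" if cfg.monitor == "val_loss" else "max"
    sched = PlateauScheduler(cfg.learning_rate, cfg.patience, cfg.lr_decay_factor, mode)
    lr = cfg.learning_rate
    for rec in history.records:
        lr = sched.step(rec[cfg.monitor])
    return lr


def _foreground_dice(pred: np.ndarray, true: np.ndarray, nc: int) -> float:
    """Mean per-sample Dice over foreground classes (both-empty counts as 1)."""
    scores = []
    for p, t in zip(pred, true):
        scores.append(np.mean([dice_coefficient(p == c, t == c) for c in range(1, nc)]))
    return float(np.mean(scores))


def _check_compat(model: FullEncoderUNet, dataset: list[SegmentationSample]) -> None:
    cfg = model.config
    for s in dataset[:1]:
        if s.image.shape[0] != cfg.n0:
            raise ValueError(
                f"dataset has {s.image.shape[0]} image channels but the model expects {cfg.n0}"
            )
    top = max(int(s.label.max()) for s in dataset)
    if top >= cfg.nc:
        raise ValueError(f"dataset labels reach class {top} but the model has nc={cfg.nc} classes")


def evaluate(model: FullEncoderUNet, dataset: list[SegmentationSample], loss_spec=None, batch_size: int = 8):
    """Validation loss and foreground Dice (no gradients; eval mode)."""
    losses, preds, trues = [], [], []
    was = model.training
    model.set_training(False)
    try:
        for start in range(0, len(dataset), batch_size):
            chunk = dataset[start : start + batch_size]
            x = np.stack([s.image for s in chunk]).astype(np.float32)
            y = np.stack([s.label for s in chunk])
            logits = model.forward(x)
            if loss_spec is not None:
                losses.append(combine_and_grad(loss_spec, logits, y)[0] * len(chunk))
            preds.append(logits.argmax(axis=1))
            trues.append(y)
    finally:
        model.set_training(was)
    pred = np.concatenate(preds)
    true = np.concatenate(trues)
    dice = _foreground_dice(pred, true, model.config.nc)
    loss = float(np.sum(losses) / len(dataset)) if losses else float("nan")
    return loss, dice


def train(
    model: FullEncoderUNet,
    train_set: list[SegmentationSample],
    val_set: list[SegmentationSample],
    cfg: TrainConfig,
    verbose: bool = False,
) -> TrainHistory:
    """Run the optimization loop; returns the history with the best-Dice state."""
    cfg.validate()
    _check_compat(model, train_set)
    _check_compat(model, val_set)
    opt = make_optimizer(model, cfg.learning_rate, cfg.weight_decay)
    sched = PlateauScheduler(
        cfg.learning_rate, cfg.patience, cfg.lr_decay_factor, "min" if cfg.monitor == "val_loss" else "max"
    )
    history = TrainHistory()
    rng = np.random.default_rng(cfg.seed)
    lr = cfg.learning_rate
    for epoch in range(1, cfg.max_epochs + 1):
        model.set_training(True)
        order = rng.permutation(len(train_set))
        epoch_loss, seen = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            x = np.stack([train_set[i].image for i in idx]).astype(np.float32)
            y = np.stack([train_set[i].label for i in idx])
            logits = model.forward(x)
            loss, grad = combine_and_grad(cfg.loss, logits, y)
            opt.zero_grad()
            model.backward(grad)
            opt.lr = lr
            opt.step()
            epoch_loss += loss * len(idx)
            seen += len(idx)
        val_loss, val_dice = evaluate(model, val_set, cfg.loss, batch_size=cfg.batch_size)
        rec = {
            "epoch": epoch,
            "train_loss": epoch_loss / max(seen, 1),
            "val_loss": val_loss,
            "val_dice": val_dice,
            "lr": lr,
        }
        history.records.append(rec)
        if val_dice > history.best_dice:
            history.best_dice = val_dice
            history.best_epoch = epoch
            history.best_state = model.state_dict()
        lr = sched.step(rec[cfg.monitor])
        if verbose:
            print(
                f"epoch {epoch:3d}  train {rec['train_loss']:.4f}  "
                f"val {val_loss:.4f}  dice {val_dice:.4f}  lr {rec['lr']:.2e}"
            )
    return history


# ---------------------------------------------------------------------------
# dataset input/output
# ---------------------------------------------------------------------------


def write_dataset(dataset: list[SegmentationSample], path: str | Path) -> None:
    """Write samples as PNG pairs plus a manifest TSV.

    3-channel images become one RGB PNG; 12-channel images become four RGB
    PNGs (one per pseudo-modality).  Labels are stored as integer-valued
    grayscale PNGs, so the label round-trip is lossless; images are quantized
    to 8 bits with the scale recorded in the manifest.
    """
    from PIL import Image

    path = Path(path)
    (path / "images").mkdir(parents=True, exist_ok=True)
    (path / "labels").mkdir(parents=True, exist_ok=True)
    rows = ["id\ttask\timage_files\tlabel_file\tscale"]
    for i, s in enumerate(dataset):
        stem = f"{i:05d}"
        c = s.image.shape[0]
        if c % 3:
            raise ValueError(f"cannot store {c}-channel image as RGB PNGs")
        files = []
        for m in range(c // 3):
            arr = np.clip(s.image[3 * m : 3 * m + 3] * 255.0 + 0.5, 0, 255).astype(np.uint8)
            name = f"{stem}.png" if c == 3 else f"{stem}_m{m}.png"
            Image.fromarray(arr.transpose(1, 2, 0)).save(path / "images" / name)
            files.append(name)
        Image.fromarray(s.label.astype(np.uint8)).save(path / "labels" / f"{stem}.png")
        rows.append(f"{stem}\t{s.meta.get('task', '')}\t{';'.join(files)}\t{stem}.png\t255")
    (path / "manifest.tsv").write_text("\n".join(rows) + "\n")


def _read_png_pairs(path: Path) -> list[SegmentationSample]:
    from PIL import Image

    manifest = path / "manifest.tsv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.tsv under {path}")
    samples = []
    for line in manifest.read_text().strip().splitlines()[1:]:
        stem, task, image_files, label_file, scale = line.split("\t")
        chans = []
        for name in image_files.split(";"):
            f = path / "images" / name
            if not f.exists():
                raise FileNotFoundError(f"missing image file {f}")
            arr = np.asarray(Image.open(f), dtype=np.float32) / float(scale)
            chans.append(arr.transpose(2, 0, 1))
        lf = path / "labels" / label_file
        if not lf.exists():
            raise FileNotFoundError(f"missing label file {lf}")
        label = np.asarray(Image.open(lf), dtype=np.int64)
        image = np.concatenate(chans)
        if image.shape[1:] != label.shape:
            raise ValueError(f"image/label shape mismatch for sample {stem}")
        samples.append(SegmentationSample(image=image, label=label, meta={"task": task, "id": stem}))
    return samples


def _read_nifti_volumes(path: Path) -> list[SegmentationSample]:
    """Slice image/label NIfTI volume pairs (paired as *_img / *_lbl) axially."""
    import nibabel as nib

    samples = []
    img_files = sorted(p for p in path.iterdir() if "_img.nii" in p.name)
    if not img_files:
        raise FileNotFoundError(f"no *_img.nii volumes under {path}")
    for img_file in img_files:
        lbl_file = Path(str(img_file).replace("_img.nii", "_lbl.nii"))
        if not lbl_file.exists():
            raise FileNotFoundError(f"missing label volume {lbl_file}")
        vol = np.asarray(nib.load(str(img_file)).dataobj, dtype=np.float32)
        lab = np.asarray(nib.load(str(lbl_file)).dataobj).astype(np.int64)
        if vol.shape != lab.shape:
            raise ValueError(f"image/label volume shape mismatch for {img_file.name}")
        lo, hi = float(vol.min()), float(vol.max())
        vol = (vol - lo) / (hi - lo) if hi > lo else np.zeros_like(vol)
        for z in range(vol.shape[-1]):
            sl = vol[..., z]
            samples.append(
                SegmentationSample(
                    image=np.repeat(sl[None], 3, axis=0),
                    label=lab[..., z],
                    meta={"volume": img_file.name, "slice": z, "scale": (lo, hi)},
                )
            )
    return samples


def read_dataset(path: str | Path, layout: str = "png_pairs") -> list[SegmentationSample]:
    path = Path(path)
    if layout == "png_pairs":
        return _read_png_pairs(path)
    if layout == "nifti_volumes":
        return _read_nifti_volumes(path)
    raise ValueError(f"unknown layout {layout!r}; use 'png_pairs' or 'nifti_volumes'")


def save_history(history: TrainHistory, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "history.tsv").write_text(history.to_tsv() + "\n")
    summary = {
        "epochs": len(history.records),
        "best_epoch": history.best_epoch,
        "best_val_dice": history.best_dice,
        "final_val_loss": history.records[-1]["val_loss"] if history.records else None,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
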