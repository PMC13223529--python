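"""Lightweight full-encoder U-shaped segmentation network.

The model is a U-shaped encoder/decoder in which *every* decoder level
receives feature maps from *all* encoder levels (full-encoder skip
connections), plus the output of the next-deeper decoder.  Channel widths are
mirrored: encoder level i and decoder level i both carry ``2**(i-1) * n``
channels, where ``n`` is the base width (8 in the lightweight configuration).

Per decoder level i each source is first resampled to scale i (non-overlapping
max-pooling downward, bilinear interpolation upward), passed through its own
single "adapter" convolution (Gamma) that maps it to the decoder width, and the
results are concatenated and fused by a two-convolution block (Theta), each
convolution followed by batch normalization and ReLU.  The level-N node is the
bottleneck shared by encoder and decoder, so at i = N-1 the deeper input *is*
the level-N encoder output and enters the concatenation once; decoder levels
below that receive N encoder maps plus one deeper decoder map (N+1 branches).

Convolutions are bias-free and batch normalization is affine-free; the final
1x1 classifier carries the only bias.  Under this convention the trainable
parameter count matches the published closed-form budget exactly (see
:mod:`feunet.param_math`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ConfigurationError, NetworkConfig
from .nn import Adam, BatchNorm2d, BilinearUpsample, Conv2d, MaxPool2d, Module, Parameter, ReLU

__all__ = [
    "FeatureMap",
    "resample",
    "decoder_layer_forward",
    "build_model",
    "FullEncoderUNet",
]


@dataclass
class FeatureMap:
    """A [channels, H, W] (or [batch, channels, H, W]) array tagged with its scale level.

    Level 1 is full resolution; each deeper level halves the spatial size.
    """

    data: np.ndarray
    level: int

    def __post_init__(self) -> None:
        if self.data.ndim not in (3, 4):
            raise ValueError("FeatureMap data must be [C,H,W] or [N,C,H,W]")
        if self.level < 1:
            raise ValueError("scale level must be >= 1")

    @property
    def channels(self) -> int:
        return self.data.shape[-3]

    @property
    def batched(self) -> np.ndarray:
        return self.data if self.data.ndim == 4 else self.data[None]


def resample(f: FeatureMap, target_level: int) -> FeatureMap:
    """Move a feature map to another scale level.

    Downward (target deeper) uses non-overlapping max-pooling with window
    ``2**(target-level)``; upward uses bilinear interpolation by the mirror
    factor; equal levels are the identity.  Channels are unchanged.
    """
    if target_level < 1:
        raise ValueError("target_level must be >= 1")
    if target_level == f.level:
        return f
    x = f.batched
    if target_level > f.level:
        window = 2 ** (target_level - f.level)
        if x.shape[-1] < window or x.shape[-2] < window:
            raise ValueError("downsampling would reduce the map below one pixel")
        y = MaxPool2d(window).forward(x)
    else:
        y = BilinearUpsample(2 ** (f.level - target_level)).forward(x)
    return FeatureMap(y if f.data.ndim == 4 else y[0], target_level)


class _ConvBNReLU(Module):
    def __init__(self, in_ch, out_ch, k, rng, name, stride=1):
        super().__init__()
        self.conv = self.add(Conv2d(in_ch, out_ch, k, stride=stride, rng=rng, name=name))
        self.bn = self.add(BatchNorm2d(out_ch))
        self.relu = self.add(ReLU())

    def forward(self, x):
        return self.relu.forward(self.bn.forward(self.conv.forward(x)))

    def backward(self, dy):
        return self.conv.backward(self.bn.backward(self.relu.backward(dy)))


class _VggStage(Module):
    """Two conv-BN-ReLU units at a fixed width (classic double-conv stage)."""

    def __init__(self, in_ch, out_ch, k, rng, name):
        super().__init__()
        self.b1 = self.add(_ConvBNReLU(in_ch, out_ch, k, rng, f"{name}.conv1"))
        self.b2 = self.add(_ConvBNReLU(out_ch, out_ch, k, rng, f"{name}.conv2"))

    def forward(self, x):
        return self.b2.forward(self.b1.forward(x))

    def backward(self, dy):
        return self.b1.backward(self.b2.backward(dy))


class _BasicBlock(Module):
    """ResNet Basic block: two 3x3 convs with an additive shortcut."""

    def __init__(self, in_ch, out_ch, k, rng, name, stride=1):
        super().__init__()
        self.conv1 = self.add(Conv2d(in_ch, out_ch, k, stride=stride, rng=rng, name=f"{name}.conv1"))
        self.bn1 = self.add(BatchNorm2d(out_ch))
        self.relu1 = self.add(ReLU())
        self.conv2 = self.add(Conv2d(out_ch, out_ch, k, rng=rng, name=f"{name}.conv2"))
        self.bn2 = self.add(BatchNorm2d(out_ch))
        self.relu2 = self.add(ReLU())
        if stride != 1 or in_ch != out_ch:
            self.proj = self.add(
                Conv2d(in_ch, out_ch, 1, stride=stride, padding=0, rng=rng, name=f"{name}.proj")
            )
            self.proj_bn = self.add(BatchNorm2d(out_ch))
        else:
            self.proj = None

    def forward(self, x):
        main = self.bn2.forward(self.conv2.forward(self.relu1.forward(self.bn1.forward(self.conv1.forward(x)))))
        short = self.proj_bn.forward(self.proj.forward(x)) if self.proj is not None else x
        return self.relu2.forward(main + short)

    def backward(self, dy):
        d = self.relu2.backward(dy)
        dx_main = self.conv1.backward(self.bn1.backward(self.relu1.backward(self.conv2.backward(self.bn2.backward(d)))))
        dx_short = self.proj.backward(self.proj_bn.backward(d)) if self.proj is not None else d
        return dx_main + dx_short


class _VggEncoder(Module):
    def __init__(self, cfg: NetworkConfig, rng):
        super().__init__()
        widths = cfg.encoder_channels()
        self.stages, self.pools = [], []
        in_ch = cfg.n0
        for i, w in enumerate(widths, start=1):
            self.stages.append(self.add(_VggStage(in_ch, w, cfg.k_e, rng, f"enc{i}")))
            if i > 1:
                self.pools.append(MaxPool2d(2))
            in_ch = w

    def forward(self, x):
        feats = []
        for i, stage in enumerate(self.stages):
            if i > 0:
                x = self.pools[i - 1].forward(x)
            x = stage.forward(x)
            feats.append(x)
        return feats

    def backward(self, dfeats):
        g = dfeats[-1]
        for i in reversed(range(len(self.stages))):
            g = self.stages[i].backward(g)
            if i > 0:
                g = self.pools[i - 1].backward(g)
                g = g + dfeats[i - 1]
        return g


class _ResNetStage(Module):
    def __init__(self, in_ch, out_ch, blocks, k, rng, name):
        super().__init__()
        self.blocks = [self.add(_BasicBlock(in_ch, out_ch, k, rng, f"{name}.block1", stride=2))]
        for b in range(1, blocks):
            self.blocks.append(self.add(_BasicBlock(out_ch, out_ch, k, rng, f"{name}.block{b + 1}")))

    def forward(self, x):
        for b in self.blocks:
            x = b.forward(x)
        return x

    def backward(self, dy):
        for b in reversed(self.blocks):
            dy = b.backward(dy)
        return dy


class _ResNetEncoder(Module):
    """3x3 stride-1 stem at width n (level 1), then four Basic-block stages."""

    def __init__(self, cfg: NetworkConfig, rng):
        super().__init__()
        widths = cfg.encoder_channels()
        self.stem = self.add(_ConvBNReLU(cfg.n0, widths[0], cfg.k_e, rng, "enc1.stem"))
        self.stages = []
        for i in range(2, cfg.N + 1):
            self.stages.append(
                self.add(_ResNetStage(widths[i - 2], widths[i - 1], cfg.w[i - 2], cfg.k_e, rng, f"enc{i}"))
            )

    def forward(self, x):
        feats = [self.stem.forward(x)]
        for stage in self.stages:
            feats.append(stage.forward(feats[-1]))
        return feats

    def backward(self, dfeats):
        g = dfeats[-1]
        for i in reversed(range(len(self.stages))):
            g = self.stages[i].backward(g) + dfeats[i]
        return self.stem.backward(g)


class _Branch(Module):
    """Resample a source to the decoder's level, then its Gamma adapter conv."""

    def __init__(self, src_level, dst_level, in_ch, out_ch, k, rng, name):
        super().__init__()
        self.src_level, self.dst_level = src_level, dst_level
        if src_level < dst_level:
            self.resampler = MaxPool2d(2 ** (dst_level - src_level))
        elif src_level > dst_level:
            self.resampler = BilinearUpsample(2 ** (src_level - dst_level))
        else:
            self.resampler = None
        self.gamma = self.add(Conv2d(in_ch, out_ch, k, rng=rng, name=name))

    def forward(self, x):
        if self.resampler is not None:
            x = self.resampler.forward(x)
        return self.gamma.forward(x)

    def backward(self, dy):
        dx = self.gamma.backward(dy)
        if self.resampler is not None:
            dx = self.resampler.backward(dx)
        return dx


class DecoderLevel(Module):
    """One decoder level: per-source Gamma branches, concat, two-conv Theta fusion."""

    def __init__(self, level: int, source_levels: list[int], source_channels: list[int], n: int, k: int, rng, name: str):
        super().__init__()
        self.level = level
        self.out_ch = n * 2 ** (level - 1)
        self.branches = [
            self.add(_Branch(sl, level, sc, self.out_ch, k, rng, f"{name}.gamma{j + 1}"))
            for j, (sl, sc) in enumerate(zip(source_levels, source_channels))
        ]
        cat = self.out_ch * len(self.branches)
        self.theta1 = self.add(_ConvBNReLU(cat, self.out_ch, k, rng, f"{name}.theta1"))
        self.theta2 = self.add(_ConvBNReLU(self.out_ch, self.out_ch, k, rng, f"{name}.theta2"))

    @property
    def num_branches(self) -> int:
        return len(self.branches)

    def forward(self, sources: list[np.ndarray]) -> np.ndarray:
        outs = [b.forward(s) for b, s in zip(self.branches, sources)]
        cat = np.concatenate(outs, axis=1)
        return self.theta2.forward(self.theta1.forward(cat))

    def backward(self, dy: np.ndarray) -> list[np.ndarray]:
        dcat = self.theta1.backward(self.theta2.backward(dy))
        grads, off = [], 0
        for b in self.branches:
            grads.append(b.backward(dcat[:, off : off + self.out_ch]))
            off += self.out_ch
        return grads


class FullEncoderUNet(Module):
    """The assembled network: backbone encoder, full-encoder decoder, 1x1 classifier."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        self.config = config.validate()
        rng = np.random.default_rng(seed)
        N = config.N
        if config.backbone == "vgg16":
            self.encoder = self.add(_VggEncoder(config, rng))
        else:
            self.encoder = self.add(_ResNetEncoder(config, rng))
        widths = config.encoder_channels()
        self.decoders: dict[int, DecoderLevel] = {}
        for i in range(N - 1, 0, -1):
            src_levels = list(range(1, N + 1))
            src_channels = list(widths)
            if i < N - 1:  # deeper decoder output; at i=N-1 the deeper IS encoder level N
                src_levels.append(i + 1)
                src_channels.append(widths[i])
            self.decoders[i] = self.add(
                DecoderLevel(i, src_levels, src_channels, config.n, config.k_e, rng, f"dec{i}")
            )
        self.classifier = self.add(
            Conv2d(config.n, config.nc, 1, padding=0, bias=True, rng=rng, name="classifier")
        )

    # -- forward/backward ---------------------------------------------------

    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[1] != self.config.n0:
            raise ValueError(
                f"expected input [batch, {self.config.n0}, H, W], got shape {x.shape}"
            )
        div = 2 ** (self.config.N - 1)
        if x.shape[2] % div or x.shape[3] % div:
            raise ValueError(f"spatial size must be divisible by {div} for N={self.config.N}")

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Return class logits [batch, nc, H, W] at the input resolution."""
        self._check_input(x)
        N = self.config.N
        if x.dtype not in (np.float32, np.float64):
            x = x.astype(np.float32)
        feats = self.encoder.forward(x)
        dec_out: dict[int, np.ndarray] = {}
        for i in range(N - 1, 0, -1):
            sources = list(feats)
            if i < N - 1:
                sources.append(dec_out[i + 1])
            dec_out[i] = self.decoders[i].forward(sources)
        self._dec_out_shape = {i: v.shape for i, v in dec_out.items()}
        return self.classifier.forward(dec_out[1])

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients given the loss gradient at the logits."""
        N = self.config.N
        dec_grads = {1: self.classifier.backward(dlogits)}
        enc_grads = [None] * N
        for i in range(1, N):
            branch_grads = self.decoders[i].backward(dec_grads.pop(i))
            for j in range(N):
                enc_grads[j] = branch_grads[j] if enc_grads[j] is None else enc_grads[j] + branch_grads[j]
            if i < N - 1:
                g = branch_grads[N]
                dec_grads[i + 1] = g if i + 1 not in dec_grads else dec_grads[i + 1] + g
        self.encoder.backward(enc_grads)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Argmax label map [batch, H, W] (runs in eval mode, restores mode)."""
        was = self.training
        self.set_training(False)
        try:
            return self.forward(x).argmax(axis=1)
        finally:
            self.set_training(was)

    # -- introspection ------------------------------------------------------

    def summary(self) -> list[dict]:
        """Per-parameter listing: name, shape, count (drives the text/JSON export)."""
        return [
            {"name": p.name, "shape": list(p.value.shape), "params": p.size}
            for p in self.parameters()
        ]

    def summary_text(self) -> str:
        lines = [f"{'layer':<28}{'shape':<22}{'params':>10}"]
        for row in self.summary():
            lines.append(f"{row['name']:<28}{str(tuple(row['shape'])):<22}{row['params']:>10}")
        lines.append(f"{'total':<50}{self.num_params():>10}")
        return "\n".join(lines)

    def state_dict(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.parameters(), state):
            p.value[...] = v


def build_model(config: NetworkConfig, seed: int = 0) -> FullEncoderUNet:
    """Construct the network for a validated configuration (seedable init)."""
    return FullEncoderUNet(config, seed=seed)


def decoder_layer_forward(
    encoder_feats: list[FeatureMap],
    deeper: FeatureMap,
    i: int,
    n: int,
    k: int = 3,
    seed: int = 0,
) -> FeatureMap:
    """Run one freshly-initialized decoder level on explicit feature maps.

    ``encoder_feats[j]`` must sit at level j+1 for j = 0..N-1; ``deeper`` is the
    level-(i+1) decoder output, or the bottleneck (the level-N encoder map)
    when i = N-1, in which case it coincides with ``encoder_feats[-1]`` and is
    fed to the concatenation once.
    """
    N = len(encoder_feats)
    if not (1 <= i <= N - 1):
        raise ValueError(f"decoder level i must be in 1..{N - 1}, got {i}")
    for j, f in enumerate(encoder_feats, start=1):
        if f.level != j:
            raise ValueError(f"encoder feature {j} is at level {f.level}, expected {j}")
    if deeper.level != i + 1:
        raise ValueError(f"deeper input is at level {deeper.level}, expected {i + 1}")
    src = [(f.level, f.channels, f.batched) for f in encoder_feats]
    if i < N - 1:
        src.append((deeper.level, deeper.channels, deeper.batched))
    rng = np.random.default_rng(seed)
    layer = DecoderLevel(i, [s[0] for s in src], [s[1] for s in src], n, k, rng, f"dec{i}")
    out = layer.forward([s[2] for s in src])
    return FeatureMap(out if encoder_feats[0].data.ndim == 4 else out[0], i)


def make_optimizer(model: FullEncoderUNet, lr: float, weight_decay: float) -> Adam:
    return Adam(model.parameters(), lr=lr, weight_decay=weight_decay)
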