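# Methods

## Architecture

The network is a U-shaped encoder/decoder with *full-encoder* skip
connections.  With N encoder levels and base width n, level i (encoder and
decoder alike) carries `d_i = 2^(i-1)·n` channels and a spatial size of
`H / 2^(i-1)`.

**Encoders.**  The VGG-style backbone uses double-conv stages: two 3×3
convolutions per level, each followed by batch normalization and ReLU, with
2×2 non-overlapping max-pooling between levels.  Depths N = 2..6 are
supported; widths double every level without a cap.  The ResNet34 backbone
uses a 3×3 stride-1 stem at width n as level 1, then four stages of Basic
blocks (two 3×3 convs plus an additive shortcut) with block counts
[3, 4, 6, 3]; the first block of each stage has stride 2 and a 1×1
projection shortcut.

**Decoder level i (1 ≤ i ≤ N−1).**  Sources are all N encoder outputs plus
the level-(i+1) decoder output.  The level-N node is the bottleneck shared
by both halves, so at i = N−1 the "deeper" input *is* the level-N encoder
output and enters the concatenation once: N+1 branches below the bottleneck,
N branches at i = N−1.  Each source is resampled to scale i (max-pooling
down, bilinear up with the half-pixel-centre convention), passed through its
own 3×3 adapter convolution Γ mapping it to `d_i` channels (bare
convolution, no normalization/activation — the adapter is a linear channel
projection; the non-linearity lives in the fusion block), concatenated, and
fused by Θ: two 3×3 convolutions (`cat → d_i`, then `d_i → d_i`), each
followed by batch normalization and ReLU.  A 1×1 convolution with bias maps
the level-1 decoder output to the nc class logits.

**Parameter counting.**  Convolutions carry no bias and batch normalization
has no learnable affine pair, so the trainable count is the convolution
weights plus the classifier's bias.  The closed form per decoder level is

    P_i = k² d_i S_i  +  k² B_i d_i²  +  k² d_i²

with S_i the summed source channels (`(2^N − 1)n` from the encoders, plus
`2^i n` from the deeper decoder when i < N−1) and B_i the branch count.
Closed form and the constructed network agree exactly; over the VGG grid
N ∈ {3..6} × n ∈ {8,16,32,64} the totals reproduce the published budget
table at 3-decimal rounding (e.g. N=5, n=8 → 0.892 M), the ResNet34
multi-class model gives 1.926 M → 1.93 M, and the derived ratios (59.02%,
3.30%, 4.43% of the reference networks' budgets) follow.  These published
totals are what fixed the conventions above — double-conv encoder stages,
the single bottleneck branch at i = N−1, Γ projecting to the decoder width,
and weights-only counting; alternatives (literal VGG16 [2,2,3,3,3] stage
depths, a duplicated bottleneck branch, channel-preserving Γ, counted
biases/affines) each fail the table by large margins.  Two open choices the
budget cannot arbitrate — whether Γ has its own activation, and the exact
bilinear corner convention — are fixed as documented above.

**Initialization** is Kaiming-normal, seeded; two builds with the same seed
are bitwise identical.

## Numerical engine

All layers are implemented on numpy with explicit backward passes:
convolution via im2col and BLAS matrix products, affine-free batch
normalization (running statistics for evaluation, momentum 0.1), max-pooling
with argmax routing, and separable bilinear interpolation expressed as two
small matrix products.  The end-to-end gradient is verified against central
finite differences in float64 in the test-suite.  Activations are float32 in
training.

## Losses

All nine losses take logits `[N_b, C, H, W]`; softmax is applied internally
except for BCL (sigmoid on raw scores).  With p the softmax output and y the
one-hot target:

* **CE** — mean over batch and pixels of −log p at the true class.
* **FL** — focal loss, −λ(1−p_t)^γ log p_t, λ = 0.25, γ = 2 by default;
  γ = 0, λ = 1 recovers CE exactly.
* **KL** — KL divergence from an ε-smoothed one-hot target (ε = 1e-8) to p.
* **L2** — mean squared error between p and y (probability space; the
  logit-space alternative is not used since every other probabilistic loss
  here is defined on p).
* **BCE** — elementwise binary cross-entropy on p per channel; the public
  `binary_cross_entropy` helper validates that direct probability inputs lie
  strictly inside (0, 1).
* **BCL** — binary cross-entropy with logits (numerically stable form).
* **DL** — soft Dice: numerator/denominator pooled over batch and pixels per
  class, averaged over classes, smoothing 1e-6.
* **TL** — Tversky with false-positive weight α = 0.3 and false-negative
  weight β = 0.7; α = β = 0.5 reduces to DL (up to the smoothing constant).
* **SF** — a soft (differentiable) F1: per-sample, per-class soft F1 averaged
  over both.  This reading is provisional — it is the standard soft-F1 form,
  distinguished from DL by its per-sample reduction — and is flagged as such.

Class reduction includes the background by default (configurable).
Combinations are weighted sums (unweighted by default); **DFK** is
DL + FL + KL.  Every loss returns an analytic gradient with respect to the
logits; the test-suite checks all of them against finite differences and
against an independently coded per-pixel oracle at 1e-6.

## Optimization

Adam (β = 0.9/0.999, ε = 1e-8) with *coupled* L2 weight decay (the decay
term is added to the raw gradient, the classic Adam convention).  Defaults
follow the reference recipe: learning rate 1e-4, weight decay 2e-3, batch
size 5, 500 epochs, and a reduce-on-plateau schedule that multiplies the
rate by 0.1 after 20 consecutive validation epochs without improvement
("iterations" are read as validation epochs; improvement is measured on the
validation loss by default, switchable to Dice).  The best-Dice parameter
state is checkpointed; there is no early stopping beyond the schedule.

## Synthetic data

The generators emulate the two tasks' shapes, not their physics:

* *liver_binary* — one bright smooth blob (elliptical-harmonic boundary,
  radius rescaled until the foreground fraction lands in the configured
  range, default 8–30%) on a textured background, contrast ≈ 0.42 against
  texture σ ≈ 0.05, three channels.  A companion volume generator stacks
  correlated slices whose organ waxes and wanes, so prominent-slice
  selection is exercisable.
* *brats_multiclass* — a brain-like ellipse containing three concentric
  compartments (enhancing core inside non-enhancing tumor inside edema), so
  the region mapping is nested by construction; four pseudo-modalities with
  distinct per-compartment contrasts, three channels each (12 total).

Preprocessing helpers mirror the real pipelines: k most prominent slices by
foreground pixel count (ties to the lower index), exclusion of multi-class
slices with fewer than 20 enhancing-tumor pixels, and a seeded 90/10 split.

The phantoms are deliberately easy — intensity thresholds nearly solve them —
so a passing smoke training shows the architecture, gradients and engine
work, *not* that the model would reach any particular accuracy on real CT or
MRI data.  Hounsfield statistics, bias fields, partial-volume effects and
anatomical variability are all absent.

## Noise model

Gaussian image noise is added in normalized [0,1] intensity space and
clipped back to [0,1] (clipping, not rescaling, keeps clean pixels
untouched).  The salt-and-pepper "variance" v_s is interpreted as the
corrupted-pixel fraction — the common imaging-toolbox convention — drawn
uniformly without replacement and split half salt / half pepper; exactly
`round(v_s · #pixels)` pixels are overwritten.  Both injectors are
deterministic under their seed, and dataset-level degradation touches the
training copy only.

## Scale of the bundled experiments

The test-suite trains the N = 5, n = 8 model on 200 phantoms at 64×64 for 3
epochs at learning rate 1e-3 (the package's choice for the small-phantom
regime, where the reference 1e-4 converges needlessly slowly), reaching
held-out Dice ≥ 0.85 — typically ≥ 0.97 — for both CE and DFK.  The
label-noise robustness check repeats this at 100 phantoms for corrupted
fractions 0, 0.1 and 0.2 and asserts the noisy runs stay within three Dice
points of the clean one, a desk-scale analogue of the published
dynamic-equilibrium behaviour.

## Known limitations

* Single-CPU numpy: minutes per small training run; no GPU, no mixed
  precision, no multi-process data loading.
* Batch normalization statistics are per-batch at batch size 5; very small
  batches give noisy evaluation statistics early in training.
* The SF loss body and the L2 target space are the provisional readings
  documented above.
* Real-data performance is out of scope: no pretrained weights, and the
  phantom results do not transfer.
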