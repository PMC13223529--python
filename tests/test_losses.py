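"""The nine losses against an independently coded per-pixel oracle.

The oracle below computes every loss with explicit Python loops straight from
the definitions (softmax per pixel, per-class overlap sums, etc.) and never
calls the vectorized implementation.
"""

import math

import numpy as np
import pytest

from feunet.config import LossSpec
from feunet.losses import (
    LOSS_NAMES,
    binary_cross_entropy,
    combine,
    combine_and_grad,
    compute_loss,
    dfk_spec,
    loss_and_grad,
)

SMOOTH, KL_EPS, CLIP = 1e-6, 1e-8, 1e-7


# --------------------------- brute-force oracle ----------------------------

def _softmax_px(zs):
    m = max(zs)
    e = [math.exp(v - m) for v in zs]
    s = sum(e)
    return [v / s for v in e]


def _probs(z):
    nb, C, H, W = z.shape
    p = np.zeros_like(z, dtype=float)
    for b in range(nb):
        for i in range(H):
            for j in range(W):
                ps = _softmax_px([z[b, c, i, j] for c in range(C)])
                for c in range(C):
                    p[b, c, i, j] = ps[c]
    return p


def _clip(v):
    return min(max(v, CLIP), 1.0 - CLIP)


def oracle_loss(name, z, y_int, spec):
    nb, C, H, W = z.shape
    y = np.zeros_like(z, dtype=float)
    for b in range(nb):
        for i in range(H):
            for j in range(W):
                y[b, y_int[b, i, j], i, j] = 1.0
    p = _probs(z)
    npix = nb * H * W
    if name == "CE":
        return -sum(
            y[b, c, i, j] * math.log(_clip(p[b, c, i, j]))
            for b in range(nb) for c in range(C) for i in range(H) for j in range(W)
        ) / npix
    if name == "FL":
        total = 0.0
        for b in range(nb):
            for i in range(H):
                for j in range(W):
                    pt = _clip(p[b, y_int[b, i, j], i, j])
                    total += -spec.lam * (1 - pt) ** spec.gamma * math.log(pt)
        return total / npix
    if name == "KL":
        total = 0.0
        for b in range(nb):
            for c in range(C):
                for i in range(H):
                    for j in range(W):
                        yt = y[b, c, i, j] * (1 - C * KL_EPS) + KL_EPS
                        total += yt * (math.log(yt) - math.log(_clip(p[b, c, i, j])))
        return total / npix
    if name == "L2":
        return sum(
            (p[b, c, i, j] - y[b, c, i, j]) ** 2
            for b in range(nb) for c in range(C) for i in range(H) for j in range(W)
        ) / (npix * C)
    if name == "BCE":
        total = 0.0
        for b in range(nb):
            for c in range(C):
                for i in range(H):
                    for j in range(W):
                        q = _clip(p[b, c, i, j])
                        total += -(y[b, c, i, j] * math.log(q) + (1 - y[b, c, i, j]) * math.log(1 - q))
        return total / (npix * C)
    if name == "BCL":
        total = 0.0
        for b in range(nb):
            for c in range(C):
                for i in range(H):
                    for j in range(W):
                        s = 1.0 / (1.0 + math.exp(-z[b, c, i, j]))
                        total += -(y[b, c, i, j] * math.log(s) + (1 - y[b, c, i, j]) * math.log(1 - s))
        return total / (npix * C)
    if name in ("DL", "TL"):
        scores = []
        for c in range(C):
            tp = sum(p[b, c, i, j] * y[b, c, i, j] for b in range(nb) for i in range(H) for j in range(W))
            if name == "DL":
                psum = sum(p[b, c, i, j] for b in range(nb) for i in range(H) for j in range(W))
                ysum = sum(y[b, c, i, j] for b in range(nb) for i in range(H) for j in range(W))
                scores.append((2 * tp + SMOOTH) / (psum + ysum + SMOOTH))
            else:
                fp = sum(p[b, c, i, j] * (1 - y[b, c, i, j]) for b in range(nb) for i in range(H) for j in range(W))
                fn = sum((1 - p[b, c, i, j]) * y[b, c, i, j] for b in range(nb) for i in range(H) for j in range(W))
                scores.append((tp + SMOOTH) / (tp + spec.alpha * fp + spec.beta * fn + SMOOTH))
        return 1.0 - sum(scores) / C
    if name == "SF":
        scores = []
        for b in range(nb):
            per_class = []
            for c in range(C):
                tp = sum(p[b, c, i, j] * y[b, c, i, j] for i in range(H) for j in range(W))
                psum = sum(p[b, c, i, j] for i in range(H) for j in range(W))
                ysum = sum(y[b, c, i, j] for i in range(H) for j in range(W))
                per_class.append((2 * tp + SMOOTH) / (psum + ysum + SMOOTH))
            scores.append(sum(per_class) / C)
        return 1.0 - sum(scores) / nb
    raise AssertionError(name)


# ------------------------------- the tests ---------------------------------

@pytest.fixture()
def seeded_example():
    rng = np.random.default_rng(1234)
    z = rng.normal(0.0, 1.5, (2, 2, 2, 2))
    y = rng.integers(0, 2, (2, 2, 2))
    return z, y


@pytest.mark.parametrize("name", LOSS_NAMES)
def test_matches_brute_force_oracle(name, seeded_example):
    z, y = seeded_example
    spec = LossSpec()
    assert compute_loss(name, z, y, spec) == pytest.approx(oracle_loss(name, z, y, spec), abs=1e-6)


@pytest.mark.parametrize("name", LOSS_NAMES)
def test_gradient_matches_finite_differences(name, seeded_example):
    z, y = seeded_example
    spec = LossSpec()
    _, g = loss_and_grad(name, z, y, spec)
    rng = np.random.default_rng(5)
    for _ in range(4):
        idx = tuple(rng.integers(0, s) for s in z.shape)
        eps = 1e-6
        zp, zm = z.copy(), z.copy()
        zp[idx] += eps
        zm[idx] -= eps
        fd = (compute_loss(name, zp, y, spec) - compute_loss(name, zm, y, spec)) / (2 * eps)
        assert abs(fd - g[idx]) < 1e-6 + 1e-4 * abs(fd)


def test_dice_loss_vanishes_at_perfect_overlap():
    # logits with a huge margin make softmax numerically one-hot
    y = np.array([[[0, 1], [1, 0]]])
    z = np.full((1, 2, 2, 2), -50.0)
    for i in range(2):
        for j in range(2):
            z[0, y[0, i, j], i, j] = 50.0
    assert compute_loss("DL", z, y) == pytest.approx(0.0, abs=1e-6)


def test_cross_entropy_of_uniform_prediction_is_log_C():
    for C in (2, 4):
        z = np.zeros((1, C, 3, 3))
        y = np.random.default_rng(0).integers(0, C, (1, 3, 3))
        assert compute_loss("CE", z, y) == pytest.approx(np.log(C), rel=1e-6)


def test_tversky_at_half_half_reduces_to_dice(seeded_example):
    z, y = seeded_example
    tl = compute_loss("TL", z, y, LossSpec(alpha=0.5, beta=0.5))
    dl = compute_loss("DL", z, y)
    assert tl == pytest.approx(dl, abs=1e-6)


def test_focal_at_gamma_zero_lambda_one_reduces_to_cross_entropy(seeded_example):
    z, y = seeded_example
    fl = compute_loss("FL", z, y, LossSpec(lam=1.0, gamma=0.0))
    assert fl == pytest.approx(compute_loss("CE", z, y), rel=1e-9)


def test_losses_nonnegative_and_minimal_at_truth(seeded_example):
    z, y = seeded_example
    sharp = np.full_like(z, -50.0)
    for b in range(z.shape[0]):
        for i in range(z.shape[2]):
            for j in range(z.shape[3]):
                sharp[b, y[b, i, j], i, j] = 50.0
    for name in LOSS_NAMES:
        random_val = compute_loss(name, z, y)
        truth_val = compute_loss(name, sharp, y)
        assert random_val >= 0.0
        assert truth_val <= random_val
        assert truth_val == pytest.approx(0.0, abs=1e-4)


def test_batch_permutation_equivariance():
    rng = np.random.default_rng(7)
    z = rng.normal(0, 1, (4, 3, 2, 2))
    y = rng.integers(0, 3, (4, 2, 2))
    perm = rng.permutation(4)
    for name in LOSS_NAMES:
        assert compute_loss(name, z, y) == pytest.approx(compute_loss(name, z[perm], y[perm]), rel=1e-9)


def test_increasing_true_class_logit_decreases_loss():
    z = np.zeros((1, 2, 1, 1))
    y = np.array([[[1]]])
    for name in ("CE", "FL", "DL", "TL"):
        lo = compute_loss(name, z, y)
        z2 = z.copy()
        z2[0, 1, 0, 0] = 2.0
        assert compute_loss(name, z2, y) < lo


class TestCombine:
    def test_singleton_equals_component(self, seeded_example):
        z, y = seeded_example
        spec = LossSpec(components=["TL"])
        assert combine(spec, z, y) == pytest.approx(compute_loss("TL", z, y, spec), rel=1e-12)

    def test_additivity_of_dl_plus_kl(self, seeded_example):
        z, y = seeded_example
        spec = LossSpec(components=["DL", "KL"])
        total = combine(spec, z, y)
        assert total == pytest.approx(
            compute_loss("DL", z, y, spec) + compute_loss("KL", z, y, spec), abs=1e-12
        )

    def test_dfk_is_sum_of_component_oracles(self, seeded_example):
        z, y = seeded_example
        spec = dfk_spec()
        expected = sum(oracle_loss(nm, z, y, spec) for nm in ("DL", "FL", "KL"))
        assert combine(spec, z, y) == pytest.approx(expected, abs=1e-6)

    def test_combined_gradient_is_weighted_sum(self, seeded_example):
        z, y = seeded_example
        spec = LossSpec(components=["CE", "DL"], weights=[2.0, 0.5])
        _, g = combine_and_grad(spec, z, y)
        expected = 2.0 * loss_and_grad("CE", z, y, spec)[1] + 0.5 * loss_and_grad("DL", z, y, spec)[1]
        np.testing.assert_allclose(g, expected, rtol=1e-12)

    def test_unknown_component_lists_valid_names(self, seeded_example):
        z, y = seeded_example
        with pytest.raises(ValueError, match="CE.*KL"):
            combine(LossSpec(components=["XX"]), z, y)


def test_bce_rejects_out_of_range_probabilities():
    probs = np.array([[0.2, 1.2], [0.5, 0.5]])
    targets = np.array([[0.0, 1.0], [1.0, 0.0]])
    with pytest.raises(ValueError, match=r"\(0, 1\)"):
        binary_cross_entropy(probs, targets)


def test_shape_mismatch_identifies_offender(seeded_example):
    z, _ = seeded_example
    with pytest.raises(ValueError, match="label shape"):
        compute_loss("CE", z, np.zeros((3, 2, 2), dtype=int))
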