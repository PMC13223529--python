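"""Structural and numerical checks of the full-encoder U-shaped network."""

import numpy as np
import pytest

from feunet.config import ConfigurationError, NetworkConfig
from feunet.architecture import FeatureMap, build_model, decoder_layer_forward, resample


class TestResample:
    def test_identity_at_same_level(self, rng):
        f = FeatureMap(rng.random((2, 8, 8), dtype=np.float32), level=2)
        out = resample(f, 2)
        np.testing.assert_array_equal(out.data, f.data)

    def test_constant_map_downsamples_to_constant(self):
        f = FeatureMap(np.full((1, 4, 4), 3.5, dtype=np.float32), level=1)
        out = resample(f, 2)
        assert out.data.shape == (1, 2, 2)
        np.testing.assert_allclose(out.data, 3.5)

    def test_downsample_matches_per_block_maximum_oracle(self, rng):
        data = rng.permutation(16).reshape(1, 4, 4).astype(np.float32)
        out = resample(FeatureMap(data, level=1), 2)
        expected = np.array(
            [[data[0, 2 * i : 2 * i + 2, 2 * j : 2 * j + 2].max() for j in range(2)] for i in range(2)]
        )
        np.testing.assert_array_equal(out.data[0], expected)

    def test_two_level_jump_uses_window_four(self, rng):
        data = rng.random((3, 8, 8), dtype=np.float32)
        out = resample(FeatureMap(data, level=1), 3)
        assert out.data.shape == (3, 2, 2)
        assert out.data[0, 0, 0] == data[0, :4, :4].max()

    def test_upsample_restores_resolution_and_channels(self, rng):
        f = FeatureMap(rng.random((5, 4, 4), dtype=np.float32), level=3)
        out = resample(f, 1)
        assert out.data.shape == (5, 16, 16)
        assert out.level == 1

    def test_upsample_preserves_constant(self):
        out = resample(FeatureMap(np.full((1, 4, 4), 2.0, dtype=np.float32), level=2), 1)
        np.testing.assert_allclose(out.data, 2.0, atol=1e-6)

    def test_too_deep_downsample_errors(self):
        f = FeatureMap(np.zeros((1, 4, 4), dtype=np.float32), level=1)
        with pytest.raises(ValueError):
            resample(f, 5)


class TestDecoderLayer:
    def _feats(self, rng, N=5, n=8, size=32):
        return [
            FeatureMap(rng.random((n * 2 ** (j - 1), size // 2 ** (j - 1), size // 2 ** (j - 1)), dtype=np.float32), j)
            for j in range(1, N + 1)
        ]

    def test_mid_level_has_n_plus_one_branches_and_mirrored_channels(self, rng):
        feats = self._feats(rng)
        deeper = FeatureMap(rng.random((32, 8, 8), dtype=np.float32), level=3)
        out = decoder_layer_forward(feats, deeper, i=2, n=8)
        assert out.channels == 16  # 2^(i-1) * n, mirroring the encoder
        assert out.level == 2
        assert out.data.shape[-1] == 16

    def test_branch_count_six_at_level_two_of_five(self, rng):
        from feunet.architecture import DecoderLevel

        model = build_model(NetworkConfig(N=5, n=8), seed=0)
        assert model.decoders[2].num_branches == 6
        assert model.decoders[4].num_branches == 5  # bottleneck enters once

    def test_bottleneck_level_accepts_encoder_top_as_deeper(self, rng):
        feats = self._feats(rng)
        out = decoder_layer_forward(feats, feats[-1], i=4, n=8)
        assert out.channels == 64

    def test_level_mismatch_raises(self, rng):
        feats = self._feats(rng)
        bad = FeatureMap(rng.random((32, 8, 8), dtype=np.float32), level=4)
        with pytest.raises(ValueError, match="level"):
            decoder_layer_forward(feats, bad, i=2, n=8)

    def test_zero_inputs_give_nonnegative_activations(self):
        feats = [
            FeatureMap(np.zeros((8 * 2 ** (j - 1), 16 // 2 ** (j - 1), 16 // 2 ** (j - 1)), dtype=np.float32), j)
            for j in range(1, 4)
        ]
        out = decoder_layer_forward(feats, feats[-1], i=2, n=8)
        assert (out.data >= 0).all()


class TestModel:
    @pytest.mark.parametrize("N", [3, 4, 5, 6])
    @pytest.mark.parametrize("n", [8, 16])
    def test_forward_shape_over_grid(self, N, n):
        size = 2 ** (N - 1) * 8
        model = build_model(NetworkConfig(N=N, n=n), seed=0)
        x = np.random.default_rng(N * 100 + n).random((1, 3, size, size), dtype=np.float32)
        out = model.forward(x)
        assert out.shape == (1, 2, size, size)

    def test_decoder_channels_mirror_encoder(self):
        cfg = NetworkConfig(N=5, n=8)
        model = build_model(cfg, seed=0)
        for i, dec in model.decoders.items():
            assert dec.out_ch == cfg.encoder_channels()[i - 1]

    def test_param_count_invariant_to_input_size(self):
        model = build_model(NetworkConfig(N=3, n=8), seed=0)
        before = model.num_params()
        model.forward(np.zeros((1, 3, 16, 16), dtype=np.float32))
        model.forward(np.zeros((1, 3, 32, 32), dtype=np.float32))
        assert model.num_params() == before

    def test_doubling_n_doubles_every_channel_dimension(self):
        s8 = build_model(NetworkConfig(N=4, n=8), seed=0).summary()
        s16 = build_model(NetworkConfig(N=4, n=16), seed=0).summary()
        assert len(s8) == len(s16)
        for a, b in zip(s8, s16):
            for da, db in zip(a["shape"], b["shape"]):
                # channel dims double; kernel dims and the fixed n0/nc stay
                assert db == 2 * da or (db == da and da in (1, 2, 3))

    def test_resnet_forward_and_shapes(self):
        model = build_model(NetworkConfig(backbone="resnet34", N=5, n=8, n0=12, nc=4), seed=0)
        x = np.random.default_rng(0).random((2, 12, 32, 32), dtype=np.float32)
        assert model.forward(x).shape == (2, 4, 32, 32)

    def test_invalid_configurations_are_named_errors(self):
        with pytest.raises(ConfigurationError, match="resnet34"):
            NetworkConfig(backbone="resnet34", N=4).validate()
        with pytest.raises(ConfigurationError, match="odd"):
            NetworkConfig(k_e=4).validate()
        with pytest.raises(ConfigurationError, match="backbone"):
            NetworkConfig(backbone="densenet").validate()
        with pytest.raises(ConfigurationError, match="2..6"):
            NetworkConfig(backbone="vgg16", N=7).validate()

    def test_indivisible_input_size_rejected(self):
        model = build_model(NetworkConfig(N=4, n=8), seed=0)
        with pytest.raises(ValueError, match="divisible"):
            model.forward(np.zeros((1, 3, 20, 20), dtype=np.float32))

    def test_seeded_init_is_reproducible(self):
        a = build_model(NetworkConfig(N=3, n=8), seed=9)
        b = build_model(NetworkConfig(N=3, n=8), seed=9)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_end_to_end_gradient_matches_finite_differences(self):
        """Backprop through encoder, branches, fusion and classifier, in float64."""
        model = build_model(NetworkConfig(N=3, n=2), seed=1)
        for p in model.parameters():
            p.value = p.value.astype(np.float64)
            p.grad = np.zeros_like(p.value)
        model.set_training(True)
        x = np.random.default_rng(2).random((2, 3, 8, 8))
        y = np.random.default_rng(3).integers(0, 2, (2, 8, 8))
        from feunet.losses import combine_and_grad
        from feunet.config import LossSpec

        spec = LossSpec(components=["CE"])

        def value():
            return combine_and_grad(spec, model.forward(x), y)[0]

        _, g = combine_and_grad(spec, model.forward(x), y)
        model.zero_grad()
        model.backward(g)
        rng = np.random.default_rng(4)
        checked = 0
        for p in rng.choice(model.parameters(), size=6, replace=False):
            idx = tuple(rng.integers(0, s) for s in p.value.shape)
            eps = 1e-5
            orig = p.value[idx]
            p.value[idx] = orig + eps
            up = value()
            p.value[idx] = orig - eps
            dn = value()
            p.value[idx] = orig
            fd = (up - dn) / (2 * eps)
            assert abs(fd - p.grad[idx]) < 1e-6 + 1e-3 * abs(fd)
            checked += 1
        assert checked == 6
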