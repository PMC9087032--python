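import math

import numpy as np
import pytest

from lumbarqc.phantom import PhantomSpec, generate_dataset, generate_phantom
from lumbarqc.metrics import dice_binary
from lumbarqc.schema import GrayImage
from lumbarqc.segnet import (ScseConfig, ScseUnet, TrainConfig, UnetConfig,
                             build_unet, channel_se, normalize_image, scse,
                             spatial_se, train, two_stage_segment)


# ---------------------------------------------------------------------------
# scalar-loop oracles

def _sigmoid(x):
    return 1.0 / (1.0 + math.exp(-x))


def _sse_oracle(m, w, b):
    h, wd, c = m.shape
    out = np.zeros_like(m, dtype=float)
    for i in range(h):
        for j in range(wd):
            q = b + sum(m[i, j, k] * w[k] for k in range(c))
            s = _sigmoid(q)
            for k in range(c):
                out[i, j, k] = m[i, j, k] * s
    return out


def _cse_oracle(m, w1, b1, w2, b2):
    h, wd, c = m.shape
    cr = w1.shape[1]
    z = [sum(m[i, j, k] for i in range(h) for j in range(wd)) / (h * wd)
         for k in range(c)]
    h1 = [max(0.0, b1[r] + sum(z[k] * w1[k, r] for k in range(c)))
          for r in range(cr)]
    u = [_sigmoid(b2[k] + sum(h1[r] * w2[r, k] for r in range(cr)))
         for k in range(c)]
    out = np.zeros_like(m, dtype=float)
    for i in range(h):
        for j in range(wd):
            for k in range(c):
                out[i, j, k] = m[i, j, k] * u[k]
    return out


@pytest.fixture()
def se_weights(rng):
    c, r = 4, 2
    return {
        "w": rng.normal(size=c), "b": 0.3,
        "w1": rng.normal(size=(c, c // r)), "b1": rng.normal(size=c // r),
        "w2": rng.normal(size=(c // r, c)), "b2": rng.normal(size=c),
    }


class TestNormalize:
    def test_full_range_unit_input_unchanged(self):
        x = np.array([[0.0, 0.25], [0.5, 1.0]])
        assert np.allclose(normalize_image(x), x)

    def test_binary_255_maps_to_unit(self):
        x = np.array([[0, 255], [255, 0]], dtype=np.uint8)
        assert set(np.unique(normalize_image(x))) == {0.0, 1.0}

    def test_16bit_matches_scalar_loop(self, rng):
        x = rng.integers(100, 60000, size=(6, 5)).astype(np.uint16)
        got = normalize_image(x)
        lo, hi = int(x.min()), int(x.max())
        for i in range(6):
            for j in range(5):
                assert got[i, j] == pytest.approx(
                    (int(x[i, j]) - lo) / (hi - lo))
        assert got.min() == 0.0 and got.max() == 1.0

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_image(np.full((8, 8), 7.0))

    def test_gray_image_keeps_position(self, ap_sample):
        out = normalize_image(GrayImage(
            np.array([[0, 2], [4, 8]]), position="AP"))
        assert out.position.value == "anteroposterior"


class TestSpatialSE:
    def test_matches_scalar_loop(self, rng, se_weights):
        m = rng.normal(size=(3, 3, 4))
        got = spatial_se(m, se_weights["w"], se_weights["b"])
        assert np.allclose(got, _sse_oracle(m, se_weights["w"],
                                            se_weights["b"]), rtol=1e-6)

    def test_identity_limit(self, rng):
        m = rng.normal(size=(4, 4, 3))
        out = spatial_se(m, np.zeros(3), bias=50.0)  # sigmoid -> 1
        assert np.allclose(out, m, atol=1e-6)

    def test_suppression_limit(self, rng):
        m = rng.normal(size=(4, 4, 3))
        out = spatial_se(m, np.zeros(3), bias=-50.0)  # sigmoid -> 0
        assert np.allclose(out, 0.0, atol=1e-6)


class TestChannelSE:
    def test_matches_scalar_loop(self, rng, se_weights):
        m = rng.normal(size=(4, 4, 4))
        got = channel_se(m, se_weights["w1"], se_weights["b1"],
                         se_weights["w2"], se_weights["b2"])
        assert np.allclose(
            got, _cse_oracle(m, se_weights["w1"], se_weights["b1"],
                             se_weights["w2"], se_weights["b2"]), rtol=1e-6)

    def test_identity_and_suppression_limits(self, rng):
        m = rng.normal(size=(4, 4, 2))
        w1 = np.zeros((2, 1))
        w2 = np.zeros((1, 2))
        near_identity = channel_se(m, w1, [0.0], w2, [50.0, 50.0])
        assert np.allclose(near_identity, m, atol=1e-6)
        one_off = channel_se(m, w1, [0.0], w2, [50.0, -50.0])
        assert np.allclose(one_off[..., 0], m[..., 0], atol=1e-6)
        assert np.allclose(one_off[..., 1], 0.0, atol=1e-6)

    def test_attenuation_never_amplifies(self, rng):
        """Channel gates lie in (0,1), so magnitudes never grow."""
        for _ in range(5):
            m = rng.normal(size=(5, 5, 4))
            out = channel_se(m, rng.normal(size=(4, 2)), rng.normal(size=2),
                             rng.normal(size=(2, 4)), rng.normal(size=4))
            assert (np.abs(out) <= np.abs(m) + 1e-12).all()


class TestScse:
    def test_combination_matches_branch_oracles(self, rng, se_weights):
        m = rng.normal(size=(5, 5, 4))
        ys = _sse_oracle(m, se_weights["w"], se_weights["b"])
        yc = _cse_oracle(m, se_weights["w1"], se_weights["b1"],
                         se_weights["w2"], se_weights["b2"])
        sse_p = (se_weights["w"], se_weights["b"])
        cse_p = (se_weights["w1"], se_weights["b1"],
                 se_weights["w2"], se_weights["b2"])
        assert np.allclose(scse(m, sse_p, cse_p, "max"),
                           np.maximum(ys, yc), rtol=1e-6)
        assert np.allclose(scse(m, sse_p, cse_p, "sum"), ys + yc, rtol=1e-6)

    def test_shape_preserved_and_unknown_mode_rejected(self, rng, se_weights):
        m = rng.normal(size=(2, 3, 4))
        sse_p = (se_weights["w"], se_weights["b"])
        cse_p = (se_weights["w1"], se_weights["b1"],
                 se_weights["w2"], se_weights["b2"])
        assert scse(m, sse_p, cse_p).shape == m.shape
        with pytest.raises(ValueError):
            scse(m, sse_p, cse_p, "mean")


class TestUnet:
    def test_output_is_probability_map(self, rng):
        cfg = UnetConfig(depth=2, base_channels=4, n_classes=5,
                         input_size=(16, 16))
        model = build_unet(cfg, seed=0)
        probs = model.forward(rng.random((2, 16, 16, 1)))
        assert probs.shape == (2, 16, 16, 5)
        assert np.allclose(probs.sum(axis=-1), 1.0, atol=1e-5)
        assert (probs >= 0).all()

    def test_input_size_divisibility(self):
        UnetConfig(depth=3, base_channels=4, input_size=(64, 64))
        with pytest.raises(ValueError, match="divisible"):
            UnetConfig(depth=3, base_channels=4, input_size=(60, 60))
        model = build_unet(UnetConfig(depth=3, base_channels=4,
                                      input_size=(64, 64)))
        with pytest.raises(ValueError):
            model.forward(np.zeros((1, 60, 60, 1)))

    def test_parameter_count_closed_form(self):
        """depth=2, base=8, 1 input channel, 2 classes, reduction 2.

        Layer-by-layer: a 3x3 conv cin->cout has (9*cin+1)*cout weights;
        an scSE block on C channels has (C+1) sSE weights plus
        C*(C/2)+(C/2)+(C/2)*C+C cSE weights.
        """
        def conv(cin, cout, k=3):
            return (k * k * cin + 1) * cout

        def scse_params(c):
            return (c + 1) + (c * (c // 2) + c // 2 + (c // 2) * c + c)

        expected = (
            conv(1, 8) + conv(8, 8) + scse_params(8)        # encoder level 1
            + conv(8, 16) + conv(16, 16) + scse_params(16)  # encoder level 2
            + conv(16, 32) + conv(32, 32)                   # bottleneck
            + conv(32, 16)                                  # up-conv level 2
            + conv(32, 16) + conv(16, 16) + scse_params(16)  # decoder level 2
            + conv(16, 8)                                   # up-conv level 1
            + conv(16, 8) + conv(8, 8) + scse_params(8)     # decoder level 1
            + conv(8, 2, k=1)                               # head
        )
        model = build_unet(UnetConfig(depth=2, base_channels=8, n_classes=2,
                                      input_size=(32, 32)))
        assert model.n_params() == expected

    def test_one_scse_block_per_coder_block(self):
        model = build_unet(UnetConfig(depth=3, base_channels=4,
                                      input_size=(32, 32)))
        assert len(model.enc_scse) == len(model.enc_blocks) == 3
        assert len(model.dec_scse) == len(model.dec_blocks) == 3

    def test_reduction_ratio_exceeding_channels_rejected(self):
        with pytest.raises(ValueError):
            UnetConfig(depth=1, base_channels=2, input_size=(16, 16),
                       scse=ScseConfig(reduction_ratio=4))


@pytest.fixture(scope="module")
def tiny_data():
    return generate_dataset(4, "AP", 1.0, seed=31, image_size=(64, 64))


class TestTraining:
    def test_loss_history_finite_and_decreasing(self, tiny_data):
        model = build_unet(UnetConfig(depth=2, base_channels=4, n_classes=2,
                                      input_size=(64, 64)), seed=1)
        hist = train(model, tiny_data,
                     TrainConfig(epochs=8, batch_size=2, seed=2,
                                 validation_fraction=0.25))
        assert len(hist["train_loss"]) == len(hist["val_loss"]) == 8
        assert all(np.isfinite(hist["train_loss"]))
        assert hist["train_loss"][-1] <= hist["train_loss"][0]

    def test_same_seed_reproduces_loss_history(self, tiny_data):
        histories = []
        for _ in range(2):
            model = build_unet(UnetConfig(depth=2, base_channels=4,
                                          n_classes=2, input_size=(64, 64)),
                               seed=5)
            histories.append(train(model, tiny_data,
                                   TrainConfig(epochs=3, batch_size=2,
                                               seed=9,
                                               validation_fraction=0.25)))
        assert histories[0] == histories[1]

    def test_overfit_single_phantom(self):
        s = generate_phantom(PhantomSpec(position="AP", seed=33,
                                         image_size=(64, 64)))
        model = build_unet(UnetConfig(depth=2, base_channels=8, n_classes=2,
                                      input_size=(64, 64)), seed=3)
        train(model, [s, s], TrainConfig(epochs=60, batch_size=2,
                                         learning_rate=2e-3, seed=4,
                                         validation_fraction=0.5))
        pred = model.predict(normalize_image(np.asarray(s.image.pixels)))
        assert dice_binary(pred == 1, s.mask.labels > 0) >= 0.95

    def test_empty_or_tiny_dataset_rejected(self):
        model = build_unet(UnetConfig(depth=2, base_channels=4,
                                      input_size=(64, 64)))
        with pytest.raises(ValueError):
            train(model, [], TrainConfig(epochs=1))


class TestTwoStage:
    @staticmethod
    def _forced(model, class_idx, strength=100.0):
        """Pin the head so every pixel gets the same argmax class."""
        b = np.full(model.config.n_classes, -strength, dtype=np.float32)
        b[class_idx] = strength
        model.head.params["W"][:] = 0.0
        model.head.params["b"] = b
        return model

    def test_empty_stage1_region_gives_all_background(self, ap_sample):
        cfg1 = UnetConfig(depth=2, base_channels=4, n_classes=2,
                          input_size=(256, 256))
        cfg2 = UnetConfig(depth=2, base_channels=4, n_classes=7,
                          input_size=(256, 256))
        s1 = self._forced(build_unet(cfg1, seed=0), 0)
        s2 = self._forced(build_unet(cfg2, seed=1), 3)
        out = two_stage_segment(ap_sample.image, s1, s2)
        assert (out.labels == 0).all()

    def test_full_stage1_region_passes_stage2_through(self, ap_sample):
        cfg1 = UnetConfig(depth=2, base_channels=4, n_classes=2,
                          input_size=(256, 256))
        cfg2 = UnetConfig(depth=2, base_channels=4, n_classes=7,
                          input_size=(256, 256))
        s1 = self._forced(build_unet(cfg1, seed=0), 1)
        s2 = self._forced(build_unet(cfg2, seed=1), 3)
        out = two_stage_segment(ap_sample.image, s1, s2)
        assert (out.labels == 3).all()

    def test_stage1_must_be_binary(self, ap_sample):
        multi = build_unet(UnetConfig(depth=2, base_channels=4, n_classes=3,
                                      input_size=(256, 256)))
        with pytest.raises(ValueError, match="binary"):
            two_stage_segment(ap_sample.image, multi, multi)
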