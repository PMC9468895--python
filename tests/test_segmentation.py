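import numpy as np
import pytest

from turstage.errors import ConfigurationError, ShapeMismatchError
from turstage.metrics import dsc
from turstage.segmentation import (
    UnetConfig,
    build_unet,
    load_checkpoint,
    predict_mask,
    save_checkpoint,
    train,
)


class TestConfig:
    def test_indivisible_in_size_rejected(self):
        with pytest.raises(ConfigurationError, match="divisible"):
            UnetConfig(depth=4, in_size=100)

    def test_bad_learning_rate(self):
        with pytest.raises(ConfigurationError, match="learning_rate"):
            UnetConfig(learning_rate=-1)

    def test_depth_bound(self):
        with pytest.raises(ConfigurationError, match="depth"):
            UnetConfig(depth=1)


class TestArchitecture:
    def test_bottleneck_channels_double_per_level(self):
        # depth 4 from base 16 -> 16*2^4 = 256 bottleneck channels
        m = build_unet(UnetConfig(depth=4, base_channels=16, in_size=16,
                                  max_epochs=1))
        w = m.bottleneck.layers[2].W.value  # second 3x3 conv of the bottleneck
        assert w.shape == (256, 256 * 9)

    def test_bottleneck_spatial_size(self):
        # input 32, depth 3 -> 32/2^3 = 4 at the bottleneck; checked via pools
        m = build_unet(UnetConfig(depth=3, base_channels=2, in_size=32,
                                  max_epochs=1))
        x = np.zeros((1, 1, 32, 32), dtype=np.float32)
        for block, pool in zip(m.enc, m.pools):
            x = pool.forward(block.forward(x, train=False), train=False)
        assert x.shape[-2:] == (4, 4)

    def test_output_shape_matches_input_with_three_classes(self):
        m = build_unet(UnetConfig(depth=2, base_channels=4, in_size=16,
                                  max_epochs=1))
        out = m.forward(np.zeros((2, 1, 16, 16), dtype=np.float32), train=False)
        assert out.shape == (2, 3, 16, 16)

    def test_parameter_count_deterministic(self):
        cfg = UnetConfig(depth=3, base_channels=8, in_size=32, max_epochs=1)
        assert build_unet(cfg).n_parameters() == build_unet(cfg).n_parameters()

    def test_seeded_init_identical(self):
        cfg = UnetConfig(depth=2, base_channels=4, in_size=16, max_epochs=1, seed=7)
        a, b = build_unet(cfg), build_unet(cfg)
        for pa, pb in zip(a.params(), b.params()):
            assert np.array_equal(pa.value, pb.value)


class TestPredict:
    def test_mask_values_in_label_set(self, rng):
        m = build_unet(UnetConfig(depth=2, base_channels=4, in_size=16, max_epochs=1))
        mask = predict_mask(m, rng.random((16, 16)))
        assert set(np.unique(mask)) <= {0, 1, 2}

    def test_inference_deterministic(self, rng):
        m = build_unet(UnetConfig(depth=2, base_channels=4, in_size=16, max_epochs=1))
        img = rng.random((16, 16))
        assert np.array_equal(predict_mask(m, img), predict_mask(m, img))

    def test_zero_weight_model_predicts_background(self, rng):
        m = build_unet(UnetConfig(depth=2, base_channels=4, in_size=16, max_epochs=1))
        for p in m.params():
            p.value[...] = 0.0
        assert (predict_mask(m, rng.random((16, 16))) == 0).all()

    def test_shape_mismatch(self):
        m = build_unet(UnetConfig(depth=2, base_channels=4, in_size=16, max_epochs=1))
        with pytest.raises(ShapeMismatchError):
            predict_mask(m, np.zeros((8, 8)))


class TestTraining:
    def test_loss_decreases_on_noiseless_slices(self, tiny_sagittal_pairs):
        cfg = UnetConfig(depth=2, base_channels=4, in_size=32, max_epochs=15,
                         patience=0, batch_size=3, seed=1)
        m = build_unet(cfg)
        _, hist = train(m, tiny_sagittal_pairs, tiny_sagittal_pairs, cfg)
        assert hist.train_loss[-1] < hist.train_loss[0]

    def test_patience_zero_runs_exactly_max_epochs(self, tiny_sagittal_pairs):
        cfg = UnetConfig(depth=2, base_channels=2, in_size=32, max_epochs=5,
                         patience=0, batch_size=3, seed=1)
        _, hist = train(build_unet(cfg), tiny_sagittal_pairs[:2],
                        tiny_sagittal_pairs[:2], cfg)
        assert hist.stopped_epoch == 5
        assert len(hist.train_loss) == 5

    def test_seed_invariance_identical_histories(self, tiny_sagittal_pairs):
        cfg = UnetConfig(depth=2, base_channels=4, in_size=32, max_epochs=4,
                         patience=0, batch_size=2, seed=11)
        _, h1 = train(build_unet(cfg), tiny_sagittal_pairs, tiny_sagittal_pairs, cfg)
        _, h2 = train(build_unet(cfg), tiny_sagittal_pairs, tiny_sagittal_pairs, cfg)
        assert h1.train_loss == h2.train_loss
        assert h1.val_loss == h2.val_loss

    def test_best_validation_loss_bounded_by_final(self, tiny_sagittal_pairs):
        cfg = UnetConfig(depth=2, base_channels=4, in_size=32, max_epochs=8,
                         patience=0, batch_size=3, seed=2)
        _, hist = train(build_unet(cfg), tiny_sagittal_pairs, tiny_sagittal_pairs, cfg)
        assert min(hist.val_loss) == hist.val_loss[hist.best_epoch - 1]
        assert hist.val_loss[hist.best_epoch - 1] <= hist.val_loss[-1] + 1e-12

    def test_empty_set_rejected(self):
        cfg = UnetConfig(depth=2, base_channels=2, in_size=32, max_epochs=1)
        with pytest.raises(ConfigurationError, match="train"):
            train(build_unet(cfg), [], [], cfg)

    def test_shape_mismatch_names_pair(self):
        cfg = UnetConfig(depth=2, base_channels=2, in_size=32, max_epochs=1)
        bad = [(np.zeros((32, 32)), np.zeros((16, 16), dtype=np.uint8))]
        with pytest.raises(ShapeMismatchError, match="pair 0"):
            train(build_unet(cfg), bad, bad, cfg)


@pytest.fixture(scope="module")
def overfit_model(tiny_sagittal_pairs):
    pairs = tiny_sagittal_pairs[:4]
    cfg = UnetConfig(depth=2, base_channels=12, in_size=32, max_epochs=300,
                     patience=0, batch_size=4, seed=0)
    model, _ = train(build_unet(cfg), pairs, pairs, cfg)
    return model, pairs


class TestCapacityAndEquivariance:
    def test_overfits_four_noiseless_slices(self, overfit_model):
        """Capacity sanity: convergence on 4 slices reaches near-perfect overlap."""
        model, pairs = overfit_model
        scores = [dsc(mask, predict_mask(model, img), s)
                  for img, mask in pairs for s in ("uterus", "tumor")]
        assert np.mean(scores) >= 0.98

    def test_flip_equivariance_after_flip_augmented_training(
            self, tiny_sagittal_pairs):
        pairs = tiny_sagittal_pairs[:4]
        cfg = UnetConfig(depth=2, base_channels=12, in_size=32, max_epochs=300,
                         patience=0, batch_size=4, seed=3, augment_flip=True)
        model, _ = train(build_unet(cfg), pairs, pairs, cfg)
        img = pairs[0][0]
        direct = predict_mask(model, img)
        unflipped = predict_mask(model, img[:, ::-1])[:, ::-1]
        for s in ("uterus", "tumor"):
            assert dsc(direct, unflipped, s) >= 0.9


def test_checkpoint_roundtrip(tmp_path, tiny_sagittal_pairs, rng):
    cfg = UnetConfig(depth=2, base_channels=4, in_size=32, max_epochs=2,
                     patience=0, batch_size=2, seed=5)
    model, _ = train(build_unet(cfg), tiny_sagittal_pairs[:2],
                     tiny_sagittal_pairs[:2], cfg)
    save_checkpoint(model, tmp_path / "m")
    loaded = load_checkpoint(tmp_path / "m")
    img = rng.random((32, 32))
    assert loaded.config == model.config
    assert np.array_equal(predict_mask(loaded, img), predict_mask(model, img))
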