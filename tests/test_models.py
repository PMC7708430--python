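"""Training recipe: loss, set composition, augmentation, UNet, training loop."""

import numpy as np
import pytest

from panseg.models import (
    TrainingConfig,
    augment_tile,
    bce_loss,
    compose_training_set,
    desk_scale_config,
    extract_class_tiles,
    predict_image,
    train_model,
)
from panseg.synthetic import LABEL_CODES, SyntheticSpec, generate_sample
from panseg.tiling import plan_grid, stitch_mean
from panseg.unet import build_unet


class TestBCELoss:
    def test_perfect_prediction_near_zero(self):
        y = np.array([1.0, 0.0, 1.0])
        assert bce_loss(y, y) < 1e-6

    def test_closed_form_ln2(self):
        assert bce_loss([1.0, 0.0], [0.5, 0.5]) == pytest.approx(np.log(2), abs=1e-12)

    def test_matches_elementwise_loop_oracle(self, rng):
        y = (rng.random(1000) > 0.5).astype(float)
        p = rng.uniform(0.001, 0.999, 1000)
        eps = 1e-7
        expected = -np.mean(
            [yi * np.log(pi) + (1 - yi) * np.log(1 - pi) for yi, pi in
             zip(y, np.clip(p, eps, 1 - eps))]
        )
        assert bce_loss(y, p) == pytest.approx(expected, abs=1e-9)

    def test_nonnegative_and_shape_checked(self, rng):
        assert bce_loss(rng.random(10) > 0.5, rng.random(10)) >= 0
        with pytest.raises(ValueError):
            bce_loss([1.0], [0.5, 0.5])


class TestComposeTrainingSet:
    def test_published_arithmetic(self):
        cfg = TrainingConfig(other_fraction=0.10, seed=0)
        rel = [("r", i) for i in range(100)]
        oth = [("o", i) for i in range(100)]
        train, heldout = compose_training_set(rel, oth, cfg)
        assert len(train) == 90 and len(heldout) == 20
        assert sum(1 for t in train if t[0] == "r") == 80
        assert sum(1 for t in train if t[0] == "o") == 10

    def test_zero_other_fraction(self):
        cfg = TrainingConfig(other_fraction=0.0, seed=0)
        train, _ = compose_training_set([1, 2, 3, 4, 5], [9, 9, 9], cfg)
        assert all(t != 9 for t in train)

    def test_seeded_partitions(self):
        rel, oth = list(range(50)), list(range(100, 130))
        a = compose_training_set(rel, oth, TrainingConfig(seed=5))
        b = compose_training_set(rel, oth, TrainingConfig(seed=5))
        c = compose_training_set(rel, oth, TrainingConfig(seed=6))
        assert a == b
        assert set(a[0]) != set(c[0]) or a[0] != c[0]  # different shuffle
        assert len(a[0]) == len(c[0]) and len(a[1]) == len(c[1])
        # partition property: train relevant + heldout = all relevant
        assert sorted([t for t in a[0] if t < 100] + a[1]) == rel

    def test_empty_relevant_rejected(self):
        with pytest.raises(ValueError):
            compose_training_set([], [1, 2], TrainingConfig())


class TestAugmentTile:
    def test_empty_ops_identity(self, rng):
        tile, mask = rng.random((16, 16, 3)), rng.random((16, 16)) > 0.5
        t2, m2 = augment_tile(tile, mask, set(), rng)
        assert np.array_equal(t2, tile) and np.array_equal(m2, mask)

    def test_flip_involution(self, rng):
        tile, mask = rng.random((16, 16, 3)), rng.random((16, 16)) > 0.5
        flipped = tile[:, ::-1], mask[:, ::-1]
        again = flipped[0][:, ::-1], flipped[1][:, ::-1]
        assert np.array_equal(again[0], tile) and np.array_equal(again[1], mask)

    def test_mask_count_preserved_flips_rotations(self, rng):
        tile, mask = rng.random((16, 16, 3)), rng.random((16, 16)) > 0.5
        for seed in range(20):
            t2, m2 = augment_tile(
                tile, mask, {"flip_h", "flip_v", "rotate"}, np.random.default_rng(seed)
            )
            assert m2.sum() == mask.sum()
            assert t2.shape == tile.shape

    def test_shear_keeps_mask_binary(self, rng):
        tile, mask = rng.random((16, 16, 3)), rng.random((16, 16)) > 0.5
        _, m2 = augment_tile(tile, mask, {"shear"}, np.random.default_rng(3))
        assert set(np.unique(m2)) <= {False, True}

    def test_unknown_op_rejected(self, rng):
        with pytest.raises(ValueError):
            augment_tile(np.zeros((4, 4, 3)), np.zeros((4, 4), bool), {"zoom"}, rng)


class TestUNet:
    def test_shape_contract(self, rng):
        net = build_unet(model_scale=4, input_size=64, depth=4, seed=0)
        out = net.forward(rng.random((1, 64, 64, 3)).astype(np.float32))
        assert out.shape == (1, 64, 64)

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError):
            build_unet(model_scale=4, input_size=66, depth=2)

    def test_zero_weights_constant_output(self, rng):
        net = build_unet(model_scale=4, input_size=32, depth=2, seed=0)
        net.set_weights([np.zeros_like(w) for w in net.get_weights()])
        p = net.predict_proba(rng.random((32, 32, 3)).astype(np.float32))
        assert np.allclose(p, 0.5)

    def test_forward_reproducible(self, rng):
        x = rng.random((2, 32, 32, 3)).astype(np.float32)
        a = build_unet(4, 32, 2, seed=9).forward(x)
        b = build_unet(4, 32, 2, seed=9).forward(x)
        assert np.allclose(a, b, atol=1e-6)


def _tile_set(seed=4, n_tiles=None):
    s = generate_sample(SyntheticSpec(image_height=128, image_width=128, seed=seed))
    img01 = s.image.astype(np.float32) / 255.0
    rel, oth = extract_class_tiles(img01, s.truth, LABEL_CODES["acinar"], 64, 32)
    return (rel[:n_tiles] if n_tiles else rel), oth


class TestTraining:
    def test_overfit_single_tile(self):
        rel, _ = _tile_set()
        tile = [rel[0]]
        cfg = desk_scale_config(epochs=200, augmentations=(), seed=0, selection="dice")
        model = train_model((tile, tile), cfg, "acinar")
        p = model.net.predict_proba(tile[0][0]) >= 0.5
        truth = tile[0][1]
        dice = 2 * (p & truth).sum() / (p.sum() + truth.sum())
        assert dice >= 0.99

    def test_loss_decreases_early(self):
        rel, oth = _tile_set()
        cfg = desk_scale_config(epochs=5, seed=1)
        model = train_model(compose_training_set(rel, oth, cfg), cfg, "acinar")
        losses = model.log["train_bce"].to_list()
        violations = sum(b > a for a, b in zip(losses, losses[1:]))
        assert violations <= 1

    def test_config_echo_and_log_columns(self):
        rel, oth = _tile_set()
        cfg = desk_scale_config(epochs=2, seed=2)
        model = train_model(compose_training_set(rel, oth, cfg), cfg, "acinar")
        assert model.config == cfg
        assert list(model.log.columns) == ["epoch", "train_bce", "val_bce", "val_dice"]
        assert len(model.log) == 2

    def test_training_reproducible(self):
        rel, oth = _tile_set()
        cfg = desk_scale_config(epochs=3, seed=7)

        def run():
            m = train_model(compose_training_set(rel, oth, cfg), cfg, "acinar")
            return m.best_epoch, m.net.predict_proba(rel[0][0])

        (e1, p1), (e2, p2) = run(), run()
        assert e1 == e2 and np.array_equal(p1, p2)

    def test_single_class_masks_warn(self):
        tiles = [(np.zeros((64, 64, 3), np.float32), np.zeros((64, 64), bool))] * 2
        cfg = desk_scale_config(epochs=1, seed=0)
        with pytest.warns(UserWarning, match="single-class"):
            train_model((tiles, tiles), cfg, "acinar")


@pytest.fixture(scope="module")
def small_model():
    rel, oth = _tile_set()
    cfg = desk_scale_config(epochs=6, seed=3)
    return train_model(compose_training_set(rel, oth, cfg), cfg, "acinar")


class TestPredictImage:
    def test_constant_image_near_constant_map(self, small_model):
        # translation invariance holds away from the zero-padded tile borders
        img = np.full((128, 128, 3), 128, np.uint8)
        p = predict_image(small_model, img)[8:-8, 8:-8]
        assert p.max() - p.min() < 0.05

    def test_equals_manual_tile_loop_oracle(self, small_model):
        s = generate_sample(SyntheticSpec(image_height=96, image_width=128, seed=9))
        p = predict_image(small_model, s.image, stride=32)
        grid = plan_grid(96, 128, 64, 32)
        img01 = s.image.astype(np.float32) / 255.0
        tiles = [small_model.net.predict_proba(t) for t in grid.cut(img01)]
        assert np.array_equal(p, stitch_mean(grid, tiles))

    def test_separation_on_synthetic_image(self, small_model):
        s = generate_sample(SyntheticSpec(image_height=128, image_width=128, seed=10))
        p = predict_image(small_model, s.image)
        acinar = s.truth == LABEL_CODES["acinar"]
        bg = s.truth == 0
        assert p[acinar].mean() > p[bg].mean()

    def test_model_tile_size_mismatch(self, small_model):
        with pytest.raises(ValueError):
            predict_image(small_model, np.zeros((40, 40, 3), np.uint8))
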