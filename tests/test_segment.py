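"""U-Net construction, training mechanics, and two-step inference."""

import numpy as np
import pytest

from xpctseg import (AnnotatedPair, LabelVolume, TrainConfig, UNetConfig,
                     VolumeImage, apply_mask, build_model, compose_two_step,
                     load_model, predict_binary, save_model, train)
from xpctseg import nn
from xpctseg.segment import pad_to_depth


TINY = UNetConfig(depth=2, base_channels=8, out_classes=2)


def _separable_pairs(n, size=32, seed=0):
    """Trivially separable two-level images: bright disk on dark ground.

    Every fourth image is specimen-free (pure background), as in a real
    scan whose end slices lie outside the sample."""
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n):
        yy, xx = np.mgrid[0:size, 0:size]
        if i % 4 == 3:
            mask = np.zeros((size, size), dtype=np.uint8)
        else:
            cy, cx = rng.uniform(0.3 * size, 0.7 * size, 2)
            r = rng.uniform(size / 6, size / 4)
            mask = ((yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2).astype(np.uint8)
        image = 0.2 + 0.6 * mask + rng.normal(0, 0.02, (size, size))
        pairs.append(AnnotatedPair(image.astype(np.float32), mask))
    return pairs


class TestBuildModel:
    def test_output_shape_and_softmax_normalisation(self):
        model = build_model(TINY, seed=0)
        x = np.random.default_rng(0).random((1, 32, 32)).astype(np.float32)
        logits = model.forward(x)
        assert logits.shape == (2, 32, 32)
        probs = nn.softmax(logits)
        np.testing.assert_allclose(probs.sum(axis=0), 1.0, rtol=1e-5)

    def test_same_seed_identical_weights(self):
        a = build_model(TINY, seed=7)
        b = build_model(TINY, seed=7)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)
        c = build_model(TINY, seed=8)
        assert any(not np.array_equal(pa.data, pc.data)
                   for pa, pc in zip(a.parameters(), c.parameters()))

    @pytest.mark.parametrize("depth,base", [(2, 4), (3, 8), (2, 8)])
    def test_parameter_count_matches_closed_form(self, depth, base):
        """Analytic parameter count for the topology: double 3x3 convs down
        and up, channel doubling per level, 1x1 head."""
        cfg = UNetConfig(depth=depth, base_channels=base, out_classes=2)
        ch = [base * 2 ** i for i in range(depth + 1)]

        def dconv(cin, cout):
            return (9 * cin * cout + cout) + (9 * cout * cout + cout)

        expected = dconv(1, ch[0])
        for i in range(1, depth):
            expected += dconv(ch[i - 1], ch[i])
        expected += dconv(ch[depth - 1], ch[depth])
        for i in reversed(range(depth)):
            expected += dconv(ch[i + 1] + ch[i], ch[i])
        expected += ch[0] * 2 + 2
        assert build_model(cfg).n_parameters() == expected

    def test_doubling_base_channels_increases_parameters(self):
        small = build_model(UNetConfig(depth=2, base_channels=4)).n_parameters()
        big = build_model(UNetConfig(depth=2, base_channels=8)).n_parameters()
        assert big > small

    def test_indivisible_input_raises(self):
        model = build_model(TINY)
        with pytest.raises(ValueError, match="2\\^depth"):
            model.forward(np.zeros((1, 30, 30), dtype=np.float32))

    def test_padding_policy_round_trip(self):
        padded, (h, w) = pad_to_depth(np.zeros((30, 29), dtype=np.float32), 2)
        assert padded.shape == (32, 32) and (h, w) == (30, 29)

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            UNetConfig(depth=1)
        with pytest.raises(ValueError):
            UNetConfig(out_classes=3)
        with pytest.raises(ValueError):
            UNetConfig(skip_connections=False)


class TestGradients:
    def test_numerical_gradient_check(self):
        """Backprop against central finite differences on a tiny net."""
        model = build_model(UNetConfig(depth=2, base_channels=2), seed=3)
        rng = np.random.default_rng(0)
        x = rng.random((1, 8, 8)).astype(np.float32)
        target = rng.integers(0, 2, (8, 8))

        def loss_fn():
            logits = model.forward(x)
            return nn.softmax_cross_entropy(logits, target)[0]

        logits = model.forward(x)
        _, dlogits, _ = nn.softmax_cross_entropy(logits, target)
        model.zero_grad()
        model.backward(dlogits)
        for p in (model.parameters()[0], model.parameters()[-2]):
            flat = p.data.reshape(-1)
            grad = p.grad.reshape(-1)
            for idx in rng.choice(flat.size, size=4, replace=False):
                eps = 1e-3
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_fn()
                flat[idx] = orig - eps
                down = loss_fn()
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert grad[idx] == pytest.approx(numeric, abs=2e-3)


class TestTraining:
    def test_easy_phantom_reaches_high_dice_and_descends(self):
        pairs = _separable_pairs(7, seed=1)
        model = build_model(TINY, seed=0)
        cfg = TrainConfig(epochs=20, seed=0, lr_initial=2e-3)
        model, log = train(model, pairs[:5], pairs[5:], cfg)
        assert log.records[-1].val_dice > 0.95
        assert log.records[-1].train_loss < log.records[0].train_loss

    def test_forced_plateau_reduces_lr_every_patience_epochs(self):
        pairs = _separable_pairs(4, size=16, seed=2)
        model = build_model(UNetConfig(depth=2, base_channels=2), seed=0)
        cfg = TrainConfig(epochs=6, seed=0, lr_initial=1e-3,
                          lr_threshold=np.inf, lr_patience_epochs=2)
        _, log = train(model, pairs[:3], pairs[3:], cfg)
        lrs = [r.lr for r in log.records]
        np.testing.assert_allclose(
            lrs, [1e-3, 1e-3, 1e-4, 1e-4, 1e-5, 1e-5], rtol=1e-9)

    def test_training_fully_reproducible_from_seed(self):
        pairs = _separable_pairs(4, size=16, seed=3)
        logs = []
        for _ in range(2):
            model = build_model(UNetConfig(depth=2, base_channels=2), seed=1)
            cfg = TrainConfig(epochs=2, seed=5, lr_initial=1e-3)
            _, log = train(model, pairs[:3], pairs[3:], cfg)
            logs.append(log.as_dicts())
        assert logs[0] == logs[1]

    def test_empty_sets_rejected(self):
        model = build_model(TINY)
        with pytest.raises(ValueError):
            train(model, [], _separable_pairs(1), TrainConfig())


@pytest.fixture(scope="module")
def trained():
    pairs = _separable_pairs(7, seed=1)
    model = build_model(TINY, seed=0)
    model, _ = train(model, pairs[:5], pairs[5:],
                     TrainConfig(epochs=20, seed=0, lr_initial=2e-3))
    return model


class TestInference:
    def test_prediction_shape_and_determinism(self, trained):
        vol = VolumeImage(np.stack([p.image for p in _separable_pairs(3, seed=9)]),
                          1.0)
        a = predict_binary(trained, vol)
        b = predict_binary(trained, vol)
        assert a.labels.shape == vol.data.shape
        np.testing.assert_array_equal(a.labels, b.labels)
        assert set(np.unique(a.labels)) <= {0, 1}

    def test_background_slice_predicts_mostly_background(self, trained):
        rng = np.random.default_rng(0)
        flat = 0.2 + rng.normal(0, 0.02, (1, 32, 32)).astype(np.float32)
        pred = predict_binary(trained, VolumeImage(flat, 1.0))
        assert pred.labels.mean() < 0.01

    def test_checkpoint_round_trip(self, trained, tmp_path):
        vol = VolumeImage(_separable_pairs(1, seed=4)[0].image[None], 1.0)
        save_model(tmp_path / "m", trained)
        loaded = load_model(tmp_path / "m")
        np.testing.assert_array_equal(predict_binary(loaded, vol).labels,
                                      predict_binary(trained, vol).labels)


class TestMaskOps:
    def test_apply_mask_identity_zero_and_checkerboard(self):
        vol = VolumeImage(np.ones((1, 4, 4), dtype=np.float32), 1.0)
        ones = LabelVolume(np.ones((1, 4, 4), dtype=np.uint8))
        zeros = LabelVolume(np.zeros((1, 4, 4), dtype=np.uint8))
        board = LabelVolume((np.indices((1, 4, 4)).sum(axis=0) % 2).astype(np.uint8))
        np.testing.assert_array_equal(apply_mask(vol, ones).data, vol.data)
        np.testing.assert_array_equal(apply_mask(vol, zeros).data, 0.0)
        assert apply_mask(vol, board).data.sum() == 8.0
        with pytest.raises(ValueError):
            apply_mask(vol, LabelVolume(np.zeros((1, 5, 5), dtype=np.uint8)))

    def test_two_step_composition_zeroes_background(self):
        rng = np.random.default_rng(0)
        step1 = LabelVolume(rng.integers(0, 2, (2, 6, 6)).astype(np.uint8))
        step2 = LabelVolume(rng.integers(0, 6, (2, 6, 6)).astype(np.uint8))
        final = compose_two_step(step1, step2)
        assert np.all(final.labels[step1.labels == 0] == 0)
        keep = step1.labels > 0
        np.testing.assert_array_equal(final.labels[keep], step2.labels[keep])
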