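"""U-Net segmenter: architecture contracts, size arithmetic, gradients,
augmentation, training behaviour, inference and serialization."""

import numpy as np
import pytest

from vascmap import nn
from vascmap import cnn_segmenter as cnn
from vascmap.classes import ARTERY, BRAIN, EXCLUDED


def _tiny_net(depth=2, mode="same", seed=0, filters=4):
    return cnn.build_unet(
        cnn.UNetConfig(depth=depth, base_filters=filters, padding_mode=mode, seed=seed)
    )


class TestArchitecture:
    def test_same_padding_shape_and_softmax(self, rng):
        net = _tiny_net()
        x = rng.random((2, 3, 32, 32)).astype(np.float32)
        logits = net.forward(x, train=False)
        assert logits.shape == (2, 32, 32, 5)
        p = nn.softmax(logits, axis=-1)
        assert np.allclose(p.sum(axis=-1), 1.0, atol=1e-5)
        assert (p >= 0).all()

    def test_seeded_builds_identical(self):
        a, b = _tiny_net(seed=5), _tiny_net(seed=5)
        for wa, wb in zip(a.weight_arrays(), b.weight_arrays()):
            np.testing.assert_array_equal(wa, wb)

    def test_wrong_channel_count_rejected(self, rng):
        net = _tiny_net()
        with pytest.raises(ValueError, match="channels"):
            net.forward(rng.random((1, 2, 32, 32)).astype(np.float32))

    def test_undersized_input_rejected(self, rng):
        net = _tiny_net(depth=3)
        with pytest.raises(ValueError, match="multiples of 8"):
            net.forward(rng.random((1, 3, 20, 20)).astype(np.float32))

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            cnn.UNetConfig(input_channels=1)
        with pytest.raises(ValueError):
            cnn.UNetConfig(output_classes=2)
        with pytest.raises(ValueError):
            cnn.UNetConfig(depth=0)


class TestValidSizeArithmetic:
    def test_total_loss_by_depth(self):
        assert [cnn.valid_total_loss(d) for d in (1, 2, 3, 4)] == [16, 40, 88, 184]

    def test_padded_input_for_512_output(self):
        assert cnn.padded_input_size(512, 4) == 696

    def test_trace_matches_classic_unet(self):
        # the canonical 572 -> 388 chain at depth 4
        sizes = cnn.valid_unet_trace(572, 4)
        assert sizes[0] == 572 and sizes[-1] == 388
        assert 28 in sizes  # bottleneck output

    def test_infeasible_trace_raises(self):
        with pytest.raises(ValueError):
            cnn.valid_unet_trace(571, 4)

    def test_paper_valid_forward_returns_input_size(self, rng):
        net = _tiny_net(depth=2, mode="paper_valid")
        x = rng.random((1, 3, 24, 24)).astype(np.float32)
        assert net.forward(x, train=False).shape == (1, 24, 24, 5)

    def test_same_padding_preserves_512(self, rng):
        net = cnn.build_unet(cnn.UNetConfig(depth=4, base_filters=4, seed=0))
        x = rng.random((1, 3, 512, 512)).astype(np.float32)
        assert net.forward(x, train=False).shape == (1, 512, 512, 5)


class TestAugmentLR:
    def test_exact_doubling_and_originals_retained(self, rng):
        images = rng.random((7, 3, 8, 8)).astype(np.float32)
        labels = rng.integers(0, 6, (7, 8, 8)).astype(np.uint8)
        ai, al = cnn.augment_lr(images, labels)
        assert ai.shape[0] == 14 and al.shape[0] == 14
        np.testing.assert_array_equal(ai[:7], images)
        np.testing.assert_array_equal(al[:7], labels)

    def test_involution(self, rng):
        images = rng.random((3, 3, 8, 8)).astype(np.float32)
        labels = rng.integers(0, 6, (3, 8, 8)).astype(np.uint8)
        ai, al = cnn.augment_lr(images, labels)
        np.testing.assert_array_equal(ai[3:][:, :, :, ::-1], images)
        np.testing.assert_array_equal(al[3:][:, :, ::-1], labels)

    def test_left_artery_mirrors_right(self):
        labels = np.zeros((1, 4, 8), dtype=np.uint8)
        labels[0, :, :4] = ARTERY  # artery only in the left half
        images = np.zeros((1, 3, 4, 8), dtype=np.float32)
        _, al = cnn.augment_lr(images, labels)
        assert (al[1][:, 4:] == ARTERY).all() and (al[1][:, :4] == 0).all()

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            cnn.augment_lr(np.zeros((0, 3, 4, 4)), np.zeros((0, 4, 4)))


class TestLoss:
    def test_zero_at_one_hot_optimum(self):
        labels = np.array([[[0, 1], [2, 3]]])
        mask = np.ones((1, 2, 2), dtype=bool)
        logits = np.full((1, 2, 2, 5), -1e3, dtype=np.float32)
        for i in range(2):
            for j in range(2):
                logits[0, i, j, labels[0, i, j]] = 1e3
        loss, grad = nn.masked_cross_entropy(logits, labels, mask)
        assert loss == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(grad, 0.0, atol=1e-6)

    def test_uniform_predictions_give_ln5(self):
        labels = np.zeros((2, 4, 4), dtype=np.int64)
        mask = np.ones((2, 4, 4), dtype=bool)
        logits = np.zeros((2, 4, 4, 5), dtype=np.float32)
        loss, _ = nn.masked_cross_entropy(logits, labels, mask)
        assert loss == pytest.approx(np.log(5.0), abs=1e-6)

    def test_excluded_voxels_contribute_nothing(self, rng):
        logits = rng.standard_normal((1, 4, 4, 5)).astype(np.float32)
        labels = rng.integers(0, 5, (1, 4, 4))
        mask = np.zeros((1, 4, 4), dtype=bool)
        mask[0, 0, 0] = True
        loss, grad = nn.masked_cross_entropy(logits, labels, mask)
        assert np.all(grad[0, 1:] == 0.0) and np.all(grad[0, 0, 1:] == 0.0)


@pytest.mark.parametrize("mode,size", [("same", 16), ("paper_valid", 24)])
def test_backward_matches_numeric_directional_derivative(mode, size):
    rng = np.random.default_rng(101)
    net = _tiny_net(depth=2, mode=mode, seed=1)
    x = rng.standard_normal((2, 3, size, size)).astype(np.float32)
    y = rng.integers(0, 5, (2, size, size))
    mask = rng.random((2, size, size)) > 0.3

    def loss_fn():
        return nn.masked_cross_entropy(net.forward(x, train=True), y, mask)

    _, d = loss_fn()
    net.backward(d)
    dirs, dot = [], 0.0
    for layer in net.param_layers():
        for (w, g) in layer.params():
            v = np.sign(g).astype(np.float32)
            dirs.append((w, v))
            dot += float((g * v).sum())
    eps = 1e-4
    for w, v in dirs:
        w += eps * v
    lp, _ = loss_fn()
    for w, v in dirs:
        w -= 2 * eps * v
    lm, _ = loss_fn()
    for w, v in dirs:
        w += eps * v
    numeric = (lp - lm) / (2 * eps)
    assert abs(numeric - dot) / abs(numeric) < 0.02


class TestTraining:
    def _toy_dataset(self, rng, n=24, size=16):
        """Two-class task solvable from intensity alone."""
        labels = np.where(rng.random((n, size, size)) > 0.5, ARTERY, BRAIN).astype(
            np.uint8
        )
        images = np.zeros((n, 3, size, size), dtype=np.float32)
        base = np.where(labels == ARTERY, 0.9, 0.4)
        for c in range(3):
            images[:, c] = np.clip(
                base + 0.02 * rng.standard_normal((n, size, size)), 0, 1
            )
        labels[:, 0, 0] = EXCLUDED  # keep the exclusion path exercised
        return images, labels

    def test_loss_decreases_and_history_recorded(self, rng):
        images, labels = self._toy_dataset(rng)
        net = _tiny_net(depth=1, filters=4)
        seg = cnn.train(
            net, images, labels,
            cnn.TrainingConfig(batch_size=6, epochs=3, seed=0),
        )
        losses = [h["loss"] for h in seg.history]
        assert len(losses) == 3
        assert losses[-1] < losses[0]
        assert len(seg.history[0]["train_dsc"]) == 5

    def test_unnormalized_images_rejected(self, rng):
        images, labels = self._toy_dataset(rng)
        with pytest.raises(ValueError, match="normalized"):
            cnn.train(_tiny_net(), images * 50, labels, cnn.TrainingConfig(epochs=1))

    def test_training_determinism(self, rng):
        images, labels = self._toy_dataset(rng, n=12)
        cfgs = cnn.TrainingConfig(batch_size=6, epochs=2, seed=4)
        a = cnn.train(_tiny_net(depth=1, seed=2), images, labels, cfgs)
        b = cnn.train(_tiny_net(depth=1, seed=2), images, labels, cfgs)
        assert [h["loss"] for h in a.history] == [h["loss"] for h in b.history]
        for wa, wb in zip(a.model.weight_arrays(), b.model.weight_arrays()):
            np.testing.assert_array_equal(wa, wb)


class TestInference:
    def test_duplicate_slices_get_identical_probabilities(self, rng):
        net = _tiny_net()
        vol = rng.random((4, 3, 16, 16)).astype(np.float32)
        vol[3] = vol[0]
        seg = cnn.TrainedSegmenter(net, net.config, cnn.TrainingConfig())
        proba = cnn.predict_proba(seg, vol, batch_size=2)
        np.testing.assert_array_equal(proba[3], proba[0])
        assert np.allclose(proba.sum(axis=-1), 1.0, atol=1e-5)

    def test_wrong_channel_count(self, rng):
        net = _tiny_net()
        seg = cnn.TrainedSegmenter(net, net.config, cnn.TrainingConfig())
        with pytest.raises(ValueError, match="slices, 3"):
            cnn.predict_proba(seg, rng.random((4, 2, 16, 16)))

    def test_assign_labels_argmax_and_ties(self):
        proba = np.zeros((1, 1, 2, 5), dtype=np.float32)
        proba[0, 0, 0] = [0.1, 0.2, 0.3, 0.25, 0.15]  # argmax -> brain (code 3)
        proba[0, 0, 1] = 0.2  # uniform tie -> artery (code 1)
        mask = np.ones((1, 1, 2), dtype=bool)
        out = cnn.assign_labels(proba, mask)
        assert out[0, 0, 0] == BRAIN
        assert out[0, 0, 1] == ARTERY

    def test_assign_labels_excludes_outside_mask(self, rng):
        proba = rng.random((2, 4, 4, 5)).astype(np.float32)
        mask = np.zeros((2, 4, 4), dtype=bool)
        out = cnn.assign_labels(proba, mask)
        assert (out == EXCLUDED).all()

    def test_assign_labels_grid_mismatch(self, rng):
        with pytest.raises(ValueError, match="grid"):
            cnn.assign_labels(rng.random((2, 4, 4, 5)), np.ones((2, 5, 4), bool))


def test_serialization_roundtrip_bit_exact(tmp_path, rng):
    net = _tiny_net(depth=2, seed=9)
    seg = cnn.TrainedSegmenter(
        net, net.config, cnn.TrainingConfig(epochs=1), history=[{"epoch": 0, "loss": 1.0}]
    )
    cnn.save_segmenter(seg, tmp_path / "model.npz")
    back = cnn.load_segmenter(tmp_path / "model.npz")
    x = rng.random((2, 3, 16, 16)).astype(np.float32)
    np.testing.assert_array_equal(
        net.forward(x, train=False), back.model.forward(x, train=False)
    )
    assert back.history == seg.history
    assert back.unet_config == seg.unet_config
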