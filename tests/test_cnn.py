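"""Image preprocessing, CNN forward/backward, training, tuning, attribution."""

import numpy as np
import pytest

from gliaplex.cnn import (
    CnnConfig,
    GlialCNN,
    attribution_maps,
    grad_cam,
    integrated_gradients,
    prepare_image,
    saliency,
    train_cnn,
    tune_cnn,
)

TINY = CnnConfig(
    conv_channels=(3, 4, 4, 4),
    hidden=(16, 8, 6),
    dropout=(0.0, 0.0, 0.0),
    input_size=32,
    max_epochs=6,
    batch_size=32,
    seed=0,
)


def _signal_images(n, n_channels=3, size=32, amplitude=1.0, seed=0):
    """Half the images carry a centered blob on channel 1: a separable set."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, n_channels, size, size))
    yy, xx = np.ogrid[:size, :size]
    blob = ((yy - size // 2) ** 2 + (xx - size // 2) ** 2 < (size // 4) ** 2).astype(float)
    y = np.r_[np.zeros(n // 2, int), np.ones(n - n // 2, int)]
    X[y == 1, 1] += amplitude * blob
    perm = rng.permutation(n)
    return X[perm], y[perm]


class TestPrepareImage:
    def test_resizes_and_standardizes(self):
        rng = np.random.default_rng(0)
        crop = rng.uniform(0, 500, (3, 20, 30))
        out = prepare_image(crop, size=64)
        assert out.shape == (3, 64, 64)
        for ch in out:
            assert abs(ch.mean()) < 1e-6
            assert abs(ch.std() - 1) < 1e-4

    def test_constant_channel_maps_to_zeros(self):
        crop = np.stack([np.full((10, 10), 7.0), np.arange(100.0).reshape(10, 10)])
        out = prepare_image(crop, size=64)
        assert np.allclose(out[0], 0.0)

    def test_standardized_64x64_input_unchanged(self):
        rng = np.random.default_rng(1)
        img = rng.standard_normal((2, 64, 64))
        img = (img - img.mean(axis=(1, 2), keepdims=True)) / img.std(axis=(1, 2), keepdims=True)
        out = prepare_image(img, size=64)
        assert np.allclose(out, img, atol=1e-6)


class TestForward:
    def test_softmax_rows_sum_to_one(self):
        net = GlialCNN(TINY, n_channels=3)
        rng = np.random.default_rng(0)
        p = net.predict_proba(rng.standard_normal((5, 3, 32, 32)))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((p > 0) & (p < 1))

    def test_batch_size_independence_in_eval(self):
        net = GlialCNN(TINY, n_channels=3)
        rng = np.random.default_rng(1)
        X = rng.standard_normal((8, 3, 32, 32))
        p_all = net.predict_proba(X, batch_size=8)
        p_split = net.predict_proba(X, batch_size=3)
        assert np.allclose(p_all, p_split, atol=1e-10)

    def test_parameter_count_matches_hand_computation(self):
        cfg = CnnConfig(conv_channels=(4, 8, 8, 8), hidden=(32, 16, 8), input_size=64, seed=0)
        net = GlialCNN(cfg, n_channels=6, n_classes=2)
        conv = (6 * 9 * 4 + 4) + (4 * 9 * 8 + 8) + (8 * 9 * 8 + 8) + (8 * 9 * 8 + 8)
        flat = 8 * 8 * 8  # conv4 channels × (64/8)²
        dense = (flat * 32 + 32) + (32 * 16 + 16) + (16 * 8 + 8) + (8 * 2 + 2)
        assert net.parameter_count() == conv + dense

    def test_gradient_matches_finite_difference(self):
        net = GlialCNN(TINY, n_channels=2)
        rng = np.random.default_rng(2)
        x = rng.standard_normal((1, 2, 32, 32))
        g = net.input_gradient(x, 1)
        eps = 1e-6
        x2 = x.copy()
        x2[0, 0, 10, 10] += eps
        num = (net.forward(x2)[0, 1] - net.forward(x)[0, 1]) / eps
        assert g[0, 0, 10, 10] == pytest.approx(num, rel=1e-4, abs=1e-8)


class TestTraining:
    def test_learns_separable_images(self):
        X, y = _signal_images(400, amplitude=1.5, seed=3)
        cfg = CnnConfig(
            conv_channels=(4, 6, 6, 6), hidden=(24, 12, 8), dropout=(0.0, 0.0, 0.0),
            input_size=32, max_epochs=10, batch_size=32, lr=2e-3, seed=3,
        )
        model, hist = train_cnn(X, y, cfg)
        assert hist["val_acc"].max() >= 0.85

    def test_single_class_training_rejected(self):
        X = np.zeros((10, 2, 32, 32))
        with pytest.raises(ValueError):
            train_cnn(X, np.zeros(10, int), TINY)

    def test_patience_honored(self):
        # pure-noise labels: validation loss stops improving quickly
        rng = np.random.default_rng(4)
        X = rng.standard_normal((80, 2, 32, 32))
        y = rng.integers(0, 2, 80)
        cfg = CnnConfig(
            conv_channels=(2, 2, 2, 2), hidden=(8, 6, 4), dropout=(0.0, 0.0, 0.0),
            input_size=32, max_epochs=40, patience=3, batch_size=32, seed=4,
        )
        model, hist = train_cnn(X, y, cfg)
        best_epoch = hist["val_loss"].idxmin()
        assert len(hist) <= hist.loc[best_epoch, "epoch"] + cfg.patience + 1

    def test_fixed_seed_reproducible(self):
        X, y = _signal_images(80, seed=5)
        cfg = CnnConfig(
            conv_channels=(2, 2, 2, 2), hidden=(8, 6, 4), input_size=32,
            max_epochs=2, batch_size=32, seed=7,
        )
        m1, h1 = train_cnn(X, y, cfg)
        m2, h2 = train_cnn(X, y, cfg)
        assert np.allclose(h1["val_loss"], h2["val_loss"])
        assert all(np.array_equal(a, b) for a, b in zip(m1.state_dict(), m2.state_dict()))


class TestTuning:
    def test_single_config_space_returns_it(self):
        X, y = _signal_images(90, seed=6)
        space = {"conv_channels": [(2, 2, 2, 2)], "hidden": [(8, 6, 4)], "max_epochs": [2],
                 "input_size": [32], "batch_size": [32]}
        model, cfg, table = tune_cnn(X, y, space, trials=1, folds=2, seed=0)
        assert cfg.conv_channels == (2, 2, 2, 2)
        assert len(table) == 1

    def test_rejects_pathological_learning_rate(self):
        X, y = _signal_images(150, amplitude=2.0, seed=7)
        space = {"lr": [2e-3, 10.0], "conv_channels": [(2, 3, 3, 3)], "hidden": [(12, 8, 6)],
                 "max_epochs": [4], "input_size": [32], "batch_size": [32],
                 "dropout": [(0.0, 0.0, 0.0)]}
        model, cfg, table = tune_cnn(X, y, space, trials=4, folds=2, seed=1)
        assert cfg.lr == pytest.approx(2e-3)
        assert table["cv_auc"].max() == table.attrs["best_cv_auc"]


@pytest.fixture(scope="module")
def net_and_image():
    net = GlialCNN(TINY, n_channels=3)
    rng = np.random.default_rng(8)
    return net, rng.standard_normal((3, 32, 32))


class TestAttribution:
    def test_integrated_gradients_completeness(self, net_and_image):
        net, img = net_and_image
        attr = integrated_gradients(net, img, class_idx=1, steps=100)
        f_x = net.forward(img[None])[0, 1]
        f_0 = net.forward(np.zeros_like(img)[None])[0, 1]
        assert attr.sum() == pytest.approx(f_x - f_0, rel=0.01)

    def test_saliency_is_absolute_input_gradient(self, net_and_image):
        net, img = net_and_image
        s = saliency(net, img, class_idx=0)
        g = net.input_gradient(img[None], 0)[0]
        assert np.allclose(s, np.abs(g))
        assert s.shape == img.shape

    def test_grad_cam_shape_and_nonnegativity(self, net_and_image):
        net, img = net_and_image
        cam = grad_cam(net, img, class_idx=1, out_size=32)
        assert cam.shape == (32, 32)
        assert cam.min() >= 0.0

    def test_attribution_bundle(self, net_and_image):
        net, img = net_and_image
        maps = attribution_maps(net, img, class_idx=0)
        assert set(maps) == {"saliency", "integrated_gradients", "grad_cam"}
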