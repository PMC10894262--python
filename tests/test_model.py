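"""HSV augmentation, model construction, training, fine-tuning, checkpoints."""

import numpy as np
import pytest

import lfaseq as L
from lfaseq.model import _prepare
from lfaseq.pipeline import load_panel


def toy_sequences(rng, n, t=6, level_signal=None):
    """Tiny synthetic ROI crops: darker G/B center band encodes the level."""
    X, y = [], []
    for i in range(n):
        level = int(rng.integers(0, 9)) if level_signal is None else \
            level_signal[i % len(level_signal)]
        frames = np.full((t, 16, 12, 3), 250, dtype=np.float64)
        frames[:, :, 4:8, 1:] -= 200.0 * level / 8.0
        frames += rng.normal(0, 1.0, frames.shape)
        X.append(np.clip(np.rint(frames), 0, 255).astype(np.uint8))
        y.append(float(level))
    return X, np.asarray(y)


class TestHsvAugment:
    def test_pure_red_maps_to_hsv_convention(self):
        frame = np.zeros((1, 4, 4, 3), dtype=np.uint8)
        frame[..., 0] = 255
        seq = L.FrameSequence(frame, np.array([10.0]))
        orig, hsv = L.hsv_augment(seq)
        assert orig is seq
        assert np.all(hsv.frames[0, :, :, 0] == 0)    # hue
        assert np.all(hsv.frames[0, :, :, 1] == 255)  # saturation
        assert np.all(hsv.frames[0, :, :, 2] == 255)  # value

    def test_gray_pixel_has_zero_saturation(self):
        frame = np.full((1, 4, 4, 3), 77, dtype=np.uint8)
        seq = L.FrameSequence(frame, np.array([10.0]))
        _, hsv = L.hsv_augment(seq)
        assert np.all(hsv.frames[0, :, :, 0] == 0)
        assert np.all(hsv.frames[0, :, :, 1] == 0)
        assert np.all(hsv.frames[0, :, :, 2] == 77)

    def test_doubles_the_training_set(self, small_panel):
        prepared = load_panel(small_panel)
        train = [p for p in prepared if p.split == "train"]
        augmented = [s for p in train for s in L.hsv_augment(p.cropped)]
        assert len(augmented) == 2 * len(train)


class TestBuildModel:
    def test_seeded_init_is_bitwise_identical(self):
        a = L.build_model(L.ModelConfig(seed=5))
        b = L.build_model(L.ModelConfig(seed=5))
        c = L.build_model(L.ModelConfig(seed=6))
        assert all(np.array_equal(a.net_.params[k], b.net_.params[k])
                   for k in a.net_.params)
        assert any(not np.array_equal(a.net_.params[k], c.net_.params[k])
                   for k in a.net_.params)

    def test_regression_head_is_scalar(self):
        model = L.build_model(L.ModelConfig(seed=0))
        rng = np.random.default_rng(0)
        X, _ = toy_sequences(rng, 2)
        assert model.predict(X).shape == (2,)

    def test_variable_sequence_lengths_accepted(self):
        model = L.build_model(L.ModelConfig(seed=0))
        rng = np.random.default_rng(0)
        X6, _ = toy_sequences(rng, 2, t=6)
        X12, _ = toy_sequences(rng, 2, t=12)
        out = model.predict(X6 + X12)
        assert out.shape == (4,) and np.all(np.isfinite(out))

    def test_invalid_dims_rejected(self):
        with pytest.raises(ValueError):
            L.ModelConfig(output_dim=3)
        with pytest.raises(ValueError):
            L.ModelConfig(feature_dim=0)
        with pytest.raises(ValueError):
            # 2 pooling stages need dims divisible by 4
            L.build_model(L.ModelConfig(input_size_px=(18, 18)))


class TestTraining:
    def test_loss_decreases_and_is_reproducible(self):
        rng = np.random.default_rng(3)
        X, y = toy_sequences(rng, 40)
        cfg = L.ModelConfig(seed=1, epochs=15)
        r1 = L.train_regressor(L.build_model(cfg), X, y)
        r2 = L.train_regressor(L.build_model(cfg), X, y)
        assert r1.train_loss[-1] < r1.train_loss[0]
        assert r1.train_loss == r2.train_loss

    def test_trained_model_orders_levels(self):
        rng = np.random.default_rng(4)
        X, y = toy_sequences(rng, 48, level_signal=[0, 8])
        model = L.build_model(L.ModelConfig(seed=0, epochs=40))
        L.train_regressor(model, X, y)
        X_test, y_test = toy_sequences(np.random.default_rng(5), 10,
                                       level_signal=[0, 8])
        scores = model.predict(X_test)
        assert scores[y_test == 8].min() > scores[y_test == 0].max()

    def test_predict_score_is_deterministic_scalar(self):
        rng = np.random.default_rng(6)
        X, y = toy_sequences(rng, 16)
        model = L.build_model(L.ModelConfig(seed=0, epochs=3))
        L.train_regressor(model, X, y)
        s1 = L.predict_score(model, X[0])
        s2 = L.predict_score(model, X[0])
        assert s1 == s2 and np.isfinite(s1)

    def test_empty_fit_rejected(self):
        model = L.build_model(L.ModelConfig(seed=0))
        with pytest.raises(ValueError):
            model.fit([], [])


@pytest.fixture(scope="module")
def pretrained():
    rng = np.random.default_rng(7)
    X, y = toy_sequences(rng, 40)
    model = L.build_model(L.ModelConfig(seed=2, epochs=20))
    L.train_regressor(model, X, y)
    return model, X, y


class TestFineTuning:
    def test_head_swap_preserves_backbone(self, pretrained):
        model, X, y = pretrained
        before = model.net_.state_dict()
        clf = L.fine_tune_binary(model, X[:8], [0, 1] * 4, epochs=1)
        assert clf.net_.out_dim == 2
        # the donor regressor is untouched
        after = model.net_.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_handoff_carries_encoder_unchanged(self, pretrained):
        """Before any gradient step the transplanted weights are bitwise equal."""
        model, X, y = pretrained
        clf = L.StripBinaryClassifier(**model.get_params())
        clf.net_ = clf._build_net(np.random.default_rng(clf.seed))
        state = model.net_.state_dict()
        for k, v in state.items():
            if not k.startswith("head_"):
                clf.net_.params[k] = v.copy()
        for k in state:
            if k.startswith("head_"):
                assert clf.net_.params[k].shape[0] == 2 or \
                    clf.net_.params[k].shape == (2,)
            else:
                assert np.array_equal(clf.net_.params[k], state[k])

    def test_separable_panel_reaches_high_accuracy(self, pretrained):
        model, _, _ = pretrained
        rng = np.random.default_rng(8)
        X, y = toy_sequences(rng, 40, level_signal=[0, 7])
        labels = (y > 0).astype(int)
        clf = L.fine_tune_binary(model, X, labels, epochs=15, seed=0)
        Xt, yt = toy_sequences(np.random.default_rng(9), 20,
                               level_signal=[0, 7])
        acc = (clf.predict(Xt) == (yt > 0)).mean()
        assert acc >= 0.9

    def test_already_binary_rejected(self, pretrained):
        model, X, y = pretrained
        clf = L.fine_tune_binary(model, X[:8], [0, 1] * 4, epochs=1)
        with pytest.raises(ValueError, match="already binary"):
            L.fine_tune_binary(clf, X[:8], [0, 1] * 4)


class TestCheckpoints:
    def test_roundtrip_preserves_predictions(self, tmp_path):
        rng = np.random.default_rng(10)
        X, y = toy_sequences(rng, 16)
        model = L.build_model(L.ModelConfig(seed=0, epochs=3))
        L.train_regressor(model, X, y)
        path = tmp_path / "model.npz"
        L.save_checkpoint(model, path)
        restored = L.load_checkpoint(path)
        assert np.array_equal(model.predict(X), restored.predict(X))
        assert restored.get_params() == model.get_params()


class TestPrepare:
    def test_rejects_malformed_samples(self):
        with pytest.raises(ValueError):
            _prepare([np.zeros((4, 4, 3))], (16, 16))
        with pytest.raises(ValueError):
            _prepare([np.zeros((0, 4, 4, 3))], (16, 16))
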