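import numpy as np
import pytest

from conftest import TINY_CNN
from eegmse.cnn import CNNFeatureExtractor, relu


class TestRelu:
    @pytest.mark.parametrize("x, expected", [(-3.0, 0.0), (2.5, 2.5), (0.0, 0.0)])
    def test_scalar(self, x, expected):
        assert relu(np.float64(x)) == expected

    def test_elementwise(self):
        np.testing.assert_array_equal(
            relu(np.array([-1.0, 0.0, 2.0])), [0.0, 0.0, 2.0]
        )


class TestForward:
    def test_default_architecture_feature_dimension(self, rng):
        """One 10 x 10 x 4 tensor maps to one 512-dimensional vector."""
        est = CNNFeatureExtractor(random_state=0).build((10, 10, 4))
        feats = est.transform(rng.standard_normal((1, 10, 10, 4)))
        assert feats.shape == (1, 512)

    def test_batch_shape(self, rng):
        est = CNNFeatureExtractor(**TINY_CNN, random_state=0).build((10, 10, 4))
        feats = est.transform(rng.standard_normal((7, 10, 10, 4)))
        assert feats.shape == (7, TINY_CNN["fc_sizes"][-1])

    def test_wrong_shape_rejected_naming_expectation(self, rng):
        est = CNNFeatureExtractor(**TINY_CNN, random_state=0).build((10, 10, 4))
        with pytest.raises(ValueError, match="10, 10, 4"):
            est.transform(rng.standard_normal((2, 9, 9, 4)))

    def test_zero_tensor_gives_zero_features(self):
        """Zero biases + rectifier linearity: all-zero input propagates to
        an all-zero feature vector."""
        est = CNNFeatureExtractor(**TINY_CNN, random_state=1).build((10, 10, 4))
        np.testing.assert_array_equal(
            est.transform(np.zeros((1, 10, 10, 4))), 0.0
        )

    def test_forward_is_deterministic_without_dropout(self, rng):
        est = CNNFeatureExtractor(**TINY_CNN, random_state=2).build((10, 10, 4))
        x = rng.standard_normal((3, 10, 10, 4))
        np.testing.assert_array_equal(est.transform(x), est.transform(x))

    def test_parameter_count_is_config_determined(self):
        a = CNNFeatureExtractor(random_state=0).build((10, 10, 4))
        b = CNNFeatureExtractor(random_state=99).build((10, 10, 4))
        assert a.n_parameters_ == b.n_parameters_
        small = CNNFeatureExtractor(**TINY_CNN, random_state=0).build((10, 10, 4))
        assert small.n_parameters_ < a.n_parameters_


def _separable_data(rng, n=256):
    X = 0.1 * rng.standard_normal((n, 10, 10, 4)).astype(np.float32)
    y = rng.integers(0, 2, n)
    X[np.arange(n), 4, 4, 0] += np.where(y == 1, 2.0, -2.0)
    return X, y


class TestTraining:
    def test_separable_problem_reaches_high_accuracy(self, rng):
        X, y = _separable_data(rng)
        cnn = CNNFeatureExtractor(
            conv_channels=(8, 16, 32, 8), fc_sizes=(64, 64),
            epochs=20, batch_size=64, random_state=0,
        ).fit(X, y)
        assert np.mean(cnn.predict(X) == y) >= 0.99

    def test_epoch_loss_broadly_decreases(self, rng):
        X, y = _separable_data(rng)
        cnn = CNNFeatureExtractor(
            conv_channels=(8, 16, 32, 8), fc_sizes=(64, 64),
            epochs=10, batch_size=64, random_state=0,
        ).fit(X, y)
        losses = [h["train_loss"] for h in cnn.history_]
        assert losses[-1] < losses[0]

    def test_lr_plateau_divides_by_ten(self, rng):
        """Once validation error stops dropping the learning rate steps
        0.01 -> 0.001 (and onward by factors of 10)."""
        X, y = _separable_data(rng)
        cnn = CNNFeatureExtractor(
            conv_channels=(8, 16, 32, 8), fc_sizes=(64, 64),
            epochs=20, batch_size=64, plateau_patience=2, random_state=0,
        ).fit(X, y)
        lrs = [h["lr"] for h in cnn.history_]
        assert lrs[0] == pytest.approx(0.01)
        assert any(lr == pytest.approx(0.001) for lr in lrs)
        # only divide-by-10 transitions ever occur
        for prev, nxt in zip(lrs, lrs[1:]):
            assert nxt == pytest.approx(prev) or nxt == pytest.approx(prev / 10)

    def test_zero_epochs_equals_initialization(self, rng):
        X, y = _separable_data(rng, n=64)
        trained = CNNFeatureExtractor(**TINY_CNN, random_state=3)
        trained.set_params(epochs=0)
        trained.fit(X, y)
        fresh = CNNFeatureExtractor(**TINY_CNN, random_state=3)
        fresh.set_params(epochs=0)
        fresh.build((10, 10, 4))
        x = rng.standard_normal((2, 10, 10, 4))
        np.testing.assert_array_equal(trained.transform(x), fresh.transform(x))

    def test_fit_is_reproducible(self, rng):
        X, y = _separable_data(rng, n=128)
        feats = []
        for _ in range(2):
            cnn = CNNFeatureExtractor(**TINY_CNN, random_state=5).fit(X, y)
            feats.append(cnn.transform(X[:4]))
        np.testing.assert_array_equal(feats[0], feats[1])

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((16, 10, 10, 4))
        with pytest.raises(ValueError, match="single class"):
            CNNFeatureExtractor(**TINY_CNN, random_state=0).fit(X, np.zeros(16))

    def test_save_load_roundtrip(self, rng, tmp_path):
        X, y = _separable_data(rng, n=64)
        cnn = CNNFeatureExtractor(**TINY_CNN, random_state=0).fit(X, y)
        path = str(tmp_path / "cnn.npz")
        cnn.save(path)
        again = CNNFeatureExtractor.load(path)
        np.testing.assert_array_equal(
            cnn.transform(X[:3]), again.transform(X[:3])
        )
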