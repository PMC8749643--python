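import numpy as np
import pytest

from oxispec import model as M
from oxispec import preprocess as pp


class TestDecodeSpo2:
    @pytest.mark.parametrize(
        "weights, expected",
        [
            (np.eye(10)[9], 99.0),  # one-hot at the top label
            ([0, 0, 0, 0, 0, 0, 0, 0, 0.5, 0.5], 98.0),  # even 97/99 split
            (np.full(10, 0.1), 90.0),  # uniform: mean of 81..99 step 2
        ],
    )
    def test_expectation_identities(self, weights, expected):
        cw = M.ClassWeights(w=np.asarray(weights, dtype=float))
        assert M.decode_spo2(cw) == pytest.approx(expected)

    def test_output_bounded_by_label_range(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            w = rng.dirichlet(np.ones(10))
            est = M.decode_spo2(M.ClassWeights(w=w))
            assert 81.0 <= est <= 99.0

    def test_shifting_mass_upward_increases_estimate(self):
        w = np.full(10, 0.1)
        for lo, hi in [(0, 9), (2, 5), (4, 8)]:
            shifted = w.copy()
            shifted[lo] -= 0.05
            shifted[hi] += 0.05
            assert M.decode_spo2(M.ClassWeights(w=shifted)) > M.decode_spo2(
                M.ClassWeights(w=w)
            )

    def test_argmax_and_expectation_agree_on_one_hot(self):
        for i in range(10):
            cw = M.ClassWeights(w=np.eye(10)[i])
            assert M.decode_spo2(cw) == float(pp.DEFAULT_LABELS[i])

    def test_invalid_weight_vector_rejected(self):
        with pytest.raises(ValueError):
            M.ClassWeights(w=np.full(10, 0.2))  # sums to 2


class TestConfig:
    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            M.CNNConfig(kernel_size=64)
        with pytest.raises(ValueError):
            M.CNNConfig(learning_rate=1.0)
        with pytest.raises(ValueError):
            M.CNNConfig(dropout_ratio=0.001)

    def test_best_reported_architecture(self):
        cfg = M.best_reported_config()
        assert (cfg.filters_block1, cfg.filters_block2) == (10, 16)
        assert cfg.n_dense_layers == 3 and cfg.dense_nodes == 40
        assert cfg.kernel_size == 6 and cfg.dropout_ratio == 0.37
        assert cfg.batch_size == 85


class TestBuildModel:
    def test_softmax_output_is_a_distribution(self):
        cfg = M.CNNConfig(epochs=10, seed=0)
        net = M.build_model(cfg, 6, 10)
        P = net.forward(np.random.default_rng(0).random((7, 6)))
        assert P.shape == (7, 10)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(P >= 0)

    def test_seeded_initialization_is_reproducible(self):
        cfg = M.CNNConfig(epochs=10, seed=5)
        x = np.random.default_rng(1).random((3, 6))
        p1 = M.build_model(cfg, 6, 10).forward(x)
        p2 = M.build_model(cfg, 6, 10).forward(x)
        assert np.array_equal(p1, p2)

    def test_three_channel_input_needs_single_block(self):
        cfg = M.CNNConfig(epochs=10)
        with pytest.raises(ValueError, match="n_blocks=1"):
            M.build_model(cfg, 3, 10)
        net = M.build_model(cfg.with_(n_blocks=1), 3, 10)
        assert net.forward(np.random.default_rng(0).random((2, 3))).shape == (2, 10)

    def test_oversized_kernel_clamped_with_warning(self):
        cfg = M.CNNConfig(kernel_size=32, epochs=10)
        with pytest.warns(UserWarning, match="clamped"):
            net = M.build_model(cfg, 6, 10)
        assert net.forward(np.random.default_rng(0).random((2, 6))).shape == (2, 10)


class TestTraining:
    def test_loss_decreases_on_separable_data(self, second_dataset):
        cfg = M.best_reported_config(epochs=15, seed=1)
        tm = M.train(M.build_model(cfg, 6, 10), second_dataset, cfg)
        assert tm.history["loss"][-1] <= tm.history["loss"][0]

    def test_training_is_deterministic_under_seed(self, second_dataset):
        cfg = M.best_reported_config(epochs=10, seed=7)
        t1 = M.train(M.build_model(cfg, 6, 10), second_dataset, cfg)
        t2 = M.train(M.build_model(cfg, 6, 10), second_dataset, cfg)
        assert np.allclose(t1.history["loss"], t2.history["loss"], atol=1e-3)

    def test_single_class_degenerate_dataset_is_learned(self, label_frames):
        ds = pp.build_dataset(
            label_frames, pp.REGIONS["SECOND"], 0.0, 50, seed=0
        )
        one = pp.LabeledDataset(
            X=ds.X[ds.y == 95.0],
            y=ds.y[ds.y == 95.0],
            region=ds.region,
            label_vector=ds.label_vector,
        )
        cfg = M.best_reported_config(
            epochs=100, seed=0, dropout_ratio=0.01, learning_rate=0.01, batch_size=10
        )
        tm = M.train(M.build_model(cfg, 6, 10), one, cfg)
        assert tm.history["accuracy"][-1] == 1.0
        assert tm.history["loss"][-1] < 0.1

    def test_width_mismatch_rejected(self, second_dataset):
        cfg = M.best_reported_config(epochs=10)
        net = M.build_model(cfg, 12, 10)
        with pytest.raises(ValueError, match="width"):
            M.train(net, second_dataset, cfg)


class TestPrediction:
    def test_weights_are_a_distribution_and_deterministic(self, trained_second_model):
        x = np.random.default_rng(3).random(6)
        w1 = M.predict_weights(trained_second_model, x)
        w2 = M.predict_weights(trained_second_model, x)
        assert w1.w.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(w1.w >= 0)
        # dropout is inference-disabled, so predictions repeat exactly
        assert np.array_equal(w1.w, w2.w)

    def test_converged_model_recovers_training_labels(
        self, trained_second_model, second_dataset
    ):
        sel = np.random.default_rng(0).choice(len(second_dataset), 50, replace=False)
        P = M.predict_batch(trained_second_model, second_dataset.X[sel])
        pred = np.asarray(trained_second_model.label_vector, float)[P.argmax(axis=1)]
        assert np.mean(pred == second_dataset.y[sel]) > 0.9

    def test_row_length_mismatch_rejected(self, trained_second_model):
        with pytest.raises(ValueError):
            M.predict_weights(trained_second_model, np.zeros(12))

    def test_decoded_output_within_label_range(self, trained_second_model, second_dataset):
        decoded = M.decode_batch(trained_second_model, second_dataset.X[:50])
        assert decoded.min() >= 81.0 and decoded.max() <= 99.0


class TestSerialization:
    def test_save_load_round_trip(self, trained_second_model, tmp_path):
        trained_second_model.save(tmp_path / "artifact")
        loaded = M.TrainedModel.load(tmp_path / "artifact")
        x = np.random.default_rng(5).random((4, 6))
        assert np.allclose(
            M.predict_batch(trained_second_model, x), M.predict_batch(loaded, x)
        )
        assert loaded.label_vector == trained_second_model.label_vector
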