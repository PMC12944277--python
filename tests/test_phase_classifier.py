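"""Dataset construction, the MLP forward pass, training, serialization."""

import numpy as np
import pytest

import gaitloop as gl
from gaitloop.gait_events import PhaseLabel
from gaitloop.kinematics import AngleSample
from gaitloop.phase_classifier import (
    CLASSES,
    LabeledDataset,
    MlpModel,
    ModelFormatError,
    build_dataset,
    count_parameters,
    load_model,
    predict,
    serialize_model,
    train,
)


def _angle_samples(angles):
    return [AngleSample(i, h, k, a, 0.0, 1.0, True) for i, (h, k, a) in enumerate(angles)]


def _cluster_dataset(n_per_class=400, seed=0):
    """Three well-separated angle clusters, one per class."""
    rng = np.random.default_rng(seed)
    centers = {PhaseLabel.STANCE: (60, 60, 60), PhaseLabel.SWING: (120, 120, 120),
               PhaseLabel.ABNORMAL: (30, 150, 30)}
    samples, labels = [], []
    for label, c in centers.items():
        pts = rng.normal(c, 3.0, size=(n_per_class, 3))
        samples.extend(pts.tolist())
        labels.extend([label] * n_per_class)
    return build_dataset([(_angle_samples(samples), labels)], seed=seed)


class TestBuildDataset:
    def test_row_count_and_source_order(self):
        angles = [(90 + i, 80, 70) for i in range(10)]
        labels = [PhaseLabel.STANCE] * 10
        ds = build_dataset([(_angle_samples(angles), labels)], seed=0)
        assert len(ds) == 10
        np.testing.assert_allclose(ds.features[:, 0], 90 + np.arange(10))

    def test_split_disjoint_and_exhaustive(self):
        ds = _cluster_dataset(100)
        assert ds.train_mask.sum() + ds.val_mask.sum() == len(ds)
        assert not np.any(ds.train_mask & ds.val_mask)
        assert ds.train_mask.sum() == round(0.8 * len(ds))

    def test_class_proportions_preserved(self):
        """No resampling: dataset priors equal the source label priors."""
        ds = _cluster_dataset(250)
        source_frac = 1 / 3
        for k in range(3):
            assert np.mean(ds.labels == k) == pytest.approx(source_frac, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_dataset([(_angle_samples([(1, 2, 3)]), [])])


class TestArchitecture:
    def test_default_parameter_count(self):
        assert count_parameters(MlpModel.initialize((3, 32, 32, 3))) == 1283

    def test_single_layer_count(self):
        assert count_parameters(MlpModel.initialize((3, 3))) == 12

    def test_count_matches_enumeration_oracle(self, rng):
        for _ in range(20):
            d, h, k = rng.integers(1, 20, size=3)
            model = MlpModel.initialize((int(d), int(h), int(k)))
            # oracle: brute-force enumeration of every weight entry
            n = sum(w.shape[0] * w.shape[1] + len(b)
                    for w, b in zip(model.weights, model.biases))
            assert count_parameters(model) == n


class TestForwardPass:
    def test_posterior_sums_to_one(self, rng):
        model = MlpModel.initialize(seed=1)
        for _ in range(20):
            p = predict(model, rng.uniform(0, 180, 3))
            assert p.p_stance + p.p_swing + p.p_abnormal == pytest.approx(1.0, abs=1e-9)

    def test_zero_weight_model_is_uniform(self):
        model = MlpModel.initialize()
        model.weights = [np.zeros_like(w) for w in model.weights]
        model.biases = [np.zeros_like(b) for b in model.biases]
        p = predict(model, (90, 90, 90))
        assert p.as_array() == pytest.approx([1 / 3] * 3, abs=1e-12)

    def test_matches_matrix_arithmetic_oracle(self, rng):
        """Forward pass equals a hand-rolled per-neuron computation."""
        for trial in range(10):
            model = MlpModel.initialize(seed=trial)
            x = rng.uniform(0, 180, 3)
            # oracle: explicit per-neuron loops, no vectorised reuse
            h = list(x)
            for w, b in zip(model.weights[:-1], model.biases[:-1]):
                h = [
                    max(0.0, sum(h[i] * w[i, j] for i in range(len(h))) + b[j])
                    for j in range(w.shape[1])
                ]
            w, b = model.weights[-1], model.biases[-1]
            logits = [
                sum(h[i] * w[i, j] for i in range(len(h))) + b[j]
                for j in range(w.shape[1])
            ]
            mx = max(logits)
            exps = [np.exp(l - mx) for l in logits]
            expected = np.array(exps) / sum(exps)
            got = predict(model, x).as_array()
            np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            predict(MlpModel.initialize(), (np.nan, 1, 2))


class TestTraining:
    def test_separable_clusters_reach_high_accuracy(self):
        ds = _cluster_dataset(400)
        model, history = train(ds, epochs_max=50, seed=0)
        assert history.val_acc[-1] >= 0.99
        assert len(history) <= 50

    def test_label_shuffle_gives_chance_accuracy(self):
        """Permutation null: no leakage beyond the class prior."""
        ds = _cluster_dataset(300)
        rng = np.random.default_rng(1)
        shuffled = LabeledDataset(
            ds.features, rng.permutation(ds.labels), ds.train_mask
        )
        model, history = train(shuffled, epochs_max=30, seed=0)
        prior = np.bincount(shuffled.labels).max() / len(shuffled)
        assert history.val_acc[-1] == pytest.approx(prior, abs=0.05)

    def test_checkpoint_restores_best_val_loss(self):
        ds = _cluster_dataset(200)
        model, history = train(ds, epochs_max=40, seed=0)
        x_va, y_va = ds.features[ds.val_mask], ds.labels[ds.val_mask]
        probs = model.forward(x_va)
        loss = -np.mean(np.log(probs[np.arange(len(y_va)), y_va]))
        assert loss == pytest.approx(min(history.val_loss), abs=1e-9)

    def test_history_bounded_by_epochs_max(self):
        ds = _cluster_dataset(50)
        _, history = train(ds, epochs_max=5, seed=0)
        assert len(history) <= 5

    def test_training_is_reproducible(self):
        ds = _cluster_dataset(100)
        m1, h1 = train(ds, epochs_max=10, seed=3)
        m2, h2 = train(ds, epochs_max=10, seed=3)
        for w1, w2 in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(w1, w2)
        assert h1.val_loss == h2.val_loss

    def test_empty_split_rejected(self):
        ds = _cluster_dataset(10)
        ds.train_mask[:] = True
        with pytest.raises(ValueError):
            train(ds, epochs_max=5)


class TestSerialization:
    def test_round_trip_bit_exact(self, tmp_path, rng):
        ds = _cluster_dataset(50)
        model, _ = train(ds, epochs_max=5, seed=0)
        path = serialize_model(model, tmp_path / "model.json")
        back = load_model(path)
        assert back.layer_sizes == (3, 32, 32, 3)
        for w1, w2 in zip(model.weights, back.weights):
            np.testing.assert_array_equal(w1, w2)
        np.testing.assert_array_equal(model.input_mean, back.input_mean)
        for _ in range(100):
            x = rng.uniform(0, 180, 3)
            np.testing.assert_array_equal(
                predict(model, x).as_array(), predict(back, x).as_array()
            )

    def test_parameter_count_preserved_by_round_trip(self, tmp_path):
        model = MlpModel.initialize()
        path = serialize_model(model, tmp_path / "m.json")
        assert count_parameters(load_model(path)) == 1283

    def test_truncated_file_is_format_error(self, tmp_path):
        path = serialize_model(MlpModel.initialize(), tmp_path / "m.json")
        path.write_text(path.read_text()[: len(path.read_text()) // 2])
        with pytest.raises(ModelFormatError):
            load_model(path)

    def test_foreign_json_rejected(self, tmp_path):
        p = tmp_path / "x.json"
        p.write_text('{"something": "else"}')
        with pytest.raises(ModelFormatError):
            load_model(p)


class TestSyntheticGaitTraining:
    def test_validation_accuracy_and_abnormal_recall(self, trained_model):
        """On geometrically separated synthetic gait, the classifier must
        recognise phases well and almost never miss an abnormal frame."""
        model, history, ds = trained_model
        probs = model.forward(ds.features[ds.val_mask])
        pred = probs.argmax(axis=1)
        y = ds.labels[ds.val_mask]
        assert np.mean(pred == y) >= 0.90
        abnormal = y == CLASSES.index(PhaseLabel.ABNORMAL)
        assert np.mean(pred[abnormal] == CLASSES.index(PhaseLabel.ABNORMAL)) >= 0.99
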