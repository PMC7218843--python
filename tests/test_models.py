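import numpy as np
import pytest

from neurovad import _lstm
from neurovad.models import (
    LstmConfig,
    SvmConfig,
    VadModel,
    predict_sequence,
    svm_isolated_classify,
    train_lstm,
)

TINY = dict(hidden_units=12, n_layers=2, max_epochs=12, patience=5, batch_size=8, time_stride=5, n_sensors=40)


def _separable_clouds(n=60, d=8, gap=8.0, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n, d))
    b = rng.standard_normal((n, d)) + gap
    X = np.vstack([a, b])
    y = np.array(["PRE"] * n + ["SPEECH"] * n)
    return X, y


def _toy_sequences(n_trials=24, T=400, snr=4.0, seed=0):
    """Feature-like sequences with a labeled elevated span."""
    rng = np.random.default_rng(seed)
    seqs, labs = [], []
    for _ in range(n_trials):
        x = rng.standard_normal((T, 4))
        x[:, 3] = rng.integers(1, 41, T)
        on = int(rng.integers(T // 4, T // 2))
        off = int(rng.integers(on + T // 8, min(on + T // 2, T - 10)))
        lab = np.zeros(T, dtype=np.int64)
        lab[on:off] = 1
        x[on:off, :3] += snr
        seqs.append(x)
        labs.append(lab)
    return seqs, labs


class TestSvm:
    def test_perfectly_separable_clouds_score_100(self):
        X, y = _separable_clouds()
        cfg = SvmConfig(class_pairings=("PRE-vs-SPEECH",))
        table = svm_isolated_classify(X, y, cfg)
        assert table["mean_accuracy"].iloc[0] == 1.0

    def test_shuffled_labels_score_near_chance(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((240, 10))
        y = np.array(["PRE", "SPEECH"] * 120)
        cfg = SvmConfig(class_pairings=("PRE-vs-SPEECH",))
        acc = svm_isolated_classify(X, y, cfg)["mean_accuracy"].iloc[0]
        # binomial 95% band around 0.5 at n=240
        assert abs(acc - 0.5) < 0.1

    def test_class_smaller_than_folds_rejected(self):
        X = np.zeros((8, 3))
        y = np.array(["PRE"] * 5 + ["SPEECH"] * 3)
        with pytest.raises(ValueError, match="fewer examples"):
            svm_isolated_classify(X, y, SvmConfig(class_pairings=("PRE-vs-SPEECH",)))

    def test_unknown_pairing_rejected(self):
        with pytest.raises(ValueError, match="unknown pairings"):
            SvmConfig(class_pairings=("CATS-vs-DOGS",))

    def test_three_class_ovo_beats_chance_on_separable_data(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.standard_normal((30, 5)) + 6 * k for k in range(3)])
        y = np.array(["PRE"] * 30 + ["SPEECH"] * 30 + ["POST"] * 30)
        cfg = SvmConfig(class_pairings=("3-CLASS-OVO",))
        assert svm_isolated_classify(X, y, cfg)["mean_accuracy"].iloc[0] > 0.95


class TestLstmTraining:
    def test_constant_label_training_predicts_constant(self):
        seqs, _ = _toy_sequences(8, T=200, seed=1)
        labs = [np.zeros(200, dtype=np.int64) for _ in seqs]
        model = train_lstm(seqs, labs, LstmConfig(**{**TINY, "max_epochs": 6}, seed=0))
        pred, probs = predict_sequence(model, seqs[0])
        assert np.all(pred == 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_learns_elevated_span(self):
        seqs, labs = _toy_sequences(24, T=400, seed=2)
        model = train_lstm(seqs[:20], labs[:20], LstmConfig(**TINY, seed=0))
        accs = []
        for x, y in zip(seqs[20:], labs[20:]):
            pred, _ = predict_sequence(model, x)
            accs.append((pred == y).mean())
        assert np.mean(accs) >= 0.9

    def test_training_is_reproducible_under_seed(self):
        seqs, labs = _toy_sequences(8, T=200, seed=3)
        cfg = LstmConfig(**{**TINY, "max_epochs": 4}, seed=7)
        m1 = train_lstm(seqs, labs, cfg)
        m2 = train_lstm(seqs, labs, cfg)
        for a, b in zip(m1.params.flat(), m2.params.flat()):
            np.testing.assert_array_equal(a, b)

    def test_mismatched_lengths_rejected(self):
        seqs, labs = _toy_sequences(4, T=100, seed=4)
        labs[0] = labs[0][:-5]
        with pytest.raises(ValueError, match="lengths differ"):
            train_lstm(seqs, labs, LstmConfig(**TINY))

    def test_fewer_than_two_trials_rejected(self):
        seqs, labs = _toy_sequences(1, T=100, seed=5)
        with pytest.raises(ValueError, match="at least 2"):
            train_lstm(seqs, labs, LstmConfig(**TINY))

    def test_label_shuffle_guard_against_leakage(self):
        # destroying the feature-label relationship must drop held-out
        # accuracy to the majority rate (no leakage/overfitting path)
        seqs, labs = _toy_sequences(16, T=200, seed=6)
        rng = np.random.default_rng(0)
        shuffled = [rng.permutation(l) for l in labs]
        model = train_lstm(seqs[:12], shuffled[:12], LstmConfig(**{**TINY, "max_epochs": 8}, seed=0))
        accs, majority = [], []
        for x, y in zip(seqs[12:], labs[12:]):
            pred, _ = predict_sequence(model, x)
            accs.append((pred == y).mean())
            majority.append(max(y.mean(), 1 - y.mean()))
        assert np.mean(accs) <= np.mean(majority) + 0.05


@pytest.fixture(scope="module")
def trained():
    seqs, labs = _toy_sequences(12, T=200, seed=8)
    model = train_lstm(seqs, labs, LstmConfig(**{**TINY, "max_epochs": 8}, seed=1))
    return model, seqs


class TestPrediction:
    def test_probabilities_sum_to_one(self, trained):
        model, seqs = trained
        _, probs = predict_sequence(model, seqs[0])
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_deterministic_at_inference(self, trained):
        model, seqs = trained
        p1 = predict_sequence(model, seqs[0])[1]
        p2 = predict_sequence(model, seqs[0])[1]
        np.testing.assert_array_equal(p1, p2)

    def test_output_length_matches_input(self, trained):
        model, seqs = trained
        labels, probs = predict_sequence(model, seqs[0])
        assert len(labels) == seqs[0].shape[0] == len(probs)

    def test_dimension_mismatch_rejected(self, trained):
        model, _ = trained
        with pytest.raises(ValueError, match="features"):
            predict_sequence(model, np.zeros((100, 7)))

    def test_save_load_predictions_bit_identical(self, trained, tmp_path):
        model, seqs = trained
        p = tmp_path / "model.npz"
        model.save(p)
        re = VadModel.load(p)
        for x in seqs[:3]:
            np.testing.assert_array_equal(predict_sequence(model, x)[1], predict_sequence(re, x)[1])
        assert re.config == model.config


class TestLstmCore:
    def test_bptt_matches_numeric_directional_derivative(self):
        rng = np.random.default_rng(3)
        params = _lstm.init_params(3, 5, 2, rng)
        x = rng.standard_normal((3, 8, 3))
        y = rng.integers(0, 2, (3, 8))
        _, grads = _lstm.loss_and_grads(params, x, y)
        dirs = [rng.standard_normal(p.shape) for p in params.flat()]
        eps = 1e-6

        def loss_at():
            p, _, _ = _lstm.forward(params, x)
            pt = np.take_along_axis(p, y[..., None], axis=-1)[..., 0]
            return float(-np.log(pt).mean())

        for p, d in zip(params.flat(), dirs):
            p += eps * d
        lp = loss_at()
        for p, d in zip(params.flat(), dirs):
            p -= 2 * eps * d
        lm = loss_at()
        num = (lp - lm) / (2 * eps)
        ana = sum(float((g * d).sum()) for g, d in zip(grads.flat(), dirs))
        assert num == pytest.approx(ana, rel=1e-6)

    def test_gradient_clip_caps_global_norm(self):
        rng = np.random.default_rng(4)
        params = _lstm.init_params(3, 4, 1, rng)
        x = rng.standard_normal((2, 5, 3)) * 10
        y = rng.integers(0, 2, (2, 5))
        _, grads = _lstm.loss_and_grads(params, x, y)
        _lstm.clip_global_norm(grads, 0.1)
        norm = np.sqrt(sum(float((g**2).sum()) for g in grads.flat()))
        assert norm <= 0.1 + 1e-12

    def test_hard_sigmoid_saturates(self):
        x = np.array([-100.0, -2.5, 0.0, 2.5, 100.0])
        np.testing.assert_allclose(_lstm.hard_sigmoid(x), [0.0, 0.0, 0.5, 1.0, 1.0])
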