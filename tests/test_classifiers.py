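import numpy as np
import pytest

from winbci.classifiers import (
    ClassifierSpec,
    LSTMCellParams,
    LSTMModel,
    lstm_cell_step,
    lstm_forward,
    predict,
    train_lstm,
    train_pointwise,
    train_rnn,
)
from winbci.windowing import PointDataset, SequenceDataset


def scalar_lstm_reference(x_seq, W, b, H, dense_W, dense_b, mean, std):
    """Element-by-element recurrence: an independent re-implementation of
    the gate equations used as oracle (no vectorized batching)."""
    import math

    sig = lambda v: 1.0 / (1.0 + math.exp(-v))
    h = [0.0] * H
    c = [0.0] * H
    for x_raw in x_seq:
        x = [(x_raw[d] - mean[d]) / std[d] for d in range(len(x_raw))]
        a = list(h) + list(x)
        z = [sum(W[r][k] * a[k] for k in range(len(a))) + b[r]
             for r in range(4 * H)]
        f = [sig(z[j]) for j in range(H)]
        i = [sig(z[H + j]) for j in range(H)]
        g = [math.tanh(z[2 * H + j]) for j in range(H)]
        o = [sig(z[3 * H + j]) for j in range(H)]
        c = [f[j] * c[j] + i[j] * g[j] for j in range(H)]
        h = [o[j] * math.tanh(c[j]) for j in range(H)]
    logits = [sum(dense_W[r][j] * h[j] for j in range(H)) + dense_b[r]
              for r in range(len(dense_b))]
    mx = max(logits)
    e = [math.exp(v - mx) for v in logits]
    s = sum(e)
    return [v / s for v in e], h, c


def random_model(rng, H=8, D=2, layers=1):
    params = []
    d = D
    for _ in range(layers):
        params.append(LSTMCellParams(rng.normal(0, 0.5, (4 * H, H + d)),
                                     rng.normal(0, 0.5, 4 * H), H))
        d = H
    return LSTMModel(params, rng.normal(0, 0.5, (2, H)), rng.normal(0, 0.5, 2))


def separable_dataset(rng, n_per_class=60, n_w=24, gap=3.0):
    """EC sequences have `gap`-times the EO mean power."""
    seqs, labels = [], []
    for _ in range(n_per_class):
        seqs.append(rng.lognormal(0.0, 0.4, (n_w, 2)))
        labels.append("EO")
        seqs.append(gap * rng.lognormal(0.0, 0.4, (n_w, 2)))
        labels.append("EC")
    return SequenceDataset(np.stack(seqs), np.array(labels, dtype="<U2"),
                           n_w / 16.0, 1, 16.0)


class TestLSTMCellStep:
    def test_zero_params_halve_cell_state(self):
        H = 4
        params = LSTMCellParams(np.zeros((4 * H, H + 2)), np.zeros(4 * H), H)
        v = np.array([1.0, -2.0, 0.5, 4.0])
        h, c = lstm_cell_step(np.zeros(2), np.zeros(H), v, params)
        np.testing.assert_allclose(c, 0.5 * v)        # f = i = 1/2, g = 0
        np.testing.assert_allclose(h, 0.5 * np.tanh(0.5 * v))

    def test_saturated_forget_gate_preserves_state(self):
        H = 3
        b = np.zeros(4 * H)
        b[:H] = 20.0                                   # forget gate ~ 1
        params = LSTMCellParams(np.zeros((4 * H, H + 2)), b, H)
        v = np.array([0.3, -0.7, 1.1])
        _, c = lstm_cell_step(np.zeros(2), np.zeros(H), v, params)
        np.testing.assert_allclose(c, v, atol=1e-6)

    def test_gate_views_match_stack(self, rng):
        H = 5
        params = LSTMCellParams(rng.normal(size=(4 * H, H + 2)),
                                rng.normal(size=4 * H), H)
        np.testing.assert_array_equal(params.W_f, params.W[:H])
        np.testing.assert_array_equal(params.W_o, params.W[3 * H:])
        np.testing.assert_array_equal(params.b_c, params.b[2 * H:3 * H])

    def test_shape_mismatch(self):
        params = LSTMCellParams(np.zeros((8, 4)), np.zeros(8), 2)
        with pytest.raises(ValueError, match="shape"):
            lstm_cell_step(np.zeros(3), np.zeros(2), np.zeros(2), params)


class TestLSTMForward:
    def test_matches_scalar_recurrence(self, rng):
        """Vectorized forward pass equals the naive scalar recurrence to
        1e-10 over random parameter draws."""
        for _ in range(10):
            H = int(rng.integers(2, 9))
            model = random_model(rng, H=H)
            model.input_mean = rng.normal(0, 1, 2)
            model.input_std = rng.uniform(0.5, 2.0, 2)
            seq = rng.lognormal(0, 1, (int(rng.integers(3, 15)), 2))
            probs = lstm_forward(model, seq)
            ref, _, _ = scalar_lstm_reference(
                seq, model.layers[0].W, model.layers[0].b, H,
                model.dense_W, model.dense_b,
                model.input_mean, model.input_std)
            np.testing.assert_allclose(probs, ref, atol=1e-10)

    def test_probabilities_sum_to_one(self, rng):
        model = random_model(rng)
        probs = lstm_forward(model, rng.lognormal(0, 1, (12, 2)))
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_dense_gives_uniform(self, rng):
        model = random_model(rng)
        model.dense_W = np.zeros_like(model.dense_W)
        model.dense_b = np.zeros_like(model.dense_b)
        probs = lstm_forward(model, rng.lognormal(0, 1, (12, 2)))
        np.testing.assert_allclose(probs, [0.5, 0.5])

    def test_output_unit_permutation_swaps_probs(self, rng):
        model = random_model(rng)
        seq = rng.lognormal(0, 1, (12, 2))
        p = lstm_forward(model, seq)
        model.dense_W = model.dense_W[::-1].copy()
        model.dense_b = model.dense_b[::-1].copy()
        np.testing.assert_allclose(lstm_forward(model, seq), p[::-1])

    def test_nan_input_rejected(self, rng):
        model = random_model(rng)
        seq = np.full((5, 2), np.nan)
        with pytest.raises(ValueError, match="NaN"):
            lstm_forward(model, seq)

    def test_serialization_round_trip(self, rng):
        model = random_model(rng, layers=2)
        seq = rng.lognormal(0, 1, (10, 2))
        back = LSTMModel.from_dict(model.to_dict())
        np.testing.assert_allclose(lstm_forward(back, seq),
                                   lstm_forward(model, seq), atol=1e-15)


class TestTrainLSTM:
    def test_separable_benchmark(self, rng):
        train = separable_dataset(rng, 60)
        val = separable_dataset(np.random.default_rng(99), 40)
        model = train_lstm(train, epochs=40, seed=0)
        acc = (predict(model, val) == val.labels).mean()
        assert acc >= 0.95

    def test_deterministic_under_seed(self, rng):
        train = separable_dataset(rng, 20, n_w=8)
        m1 = train_lstm(train, epochs=5, seed=3)
        m2 = train_lstm(train, epochs=5, seed=3)
        np.testing.assert_array_equal(m1.layers[0].W, m2.layers[0].W)
        np.testing.assert_array_equal(m1.dense_W, m2.dense_W)

    def test_loss_decreases(self, rng):
        train = separable_dataset(rng, 30, n_w=12)
        model = train_lstm(train, epochs=30, seed=1)
        assert model.loss_history[-1] < model.loss_history[0]

    def test_two_layer_trains_and_holds_up(self, rng):
        train = separable_dataset(rng, 50)
        val = separable_dataset(np.random.default_rng(7), 40)
        one = train_lstm(train, n_layers=1, epochs=40, seed=0)
        two = train_lstm(train, n_layers=2, epochs=40, seed=0)
        acc1 = (predict(one, val) == val.labels).mean()
        acc2 = (predict(two, val) == val.labels).mean()
        assert acc2 >= acc1 - 0.02
        assert two.n_layers == 2

    def test_single_class_rejected(self, rng):
        ds = separable_dataset(rng, 10, n_w=8)
        only = ds.subset(np.flatnonzero(ds.labels == "EO"))
        with pytest.raises(ValueError, match="both classes"):
            train_lstm(only, epochs=1)


class TestTapDelayRNN:
    def test_above_chance_on_separable(self, rng):
        train = separable_dataset(rng, 50)
        val = separable_dataset(np.random.default_rng(5), 40)
        model = train_rnn(train, delay_s=0.5, epochs=40, seed=0)
        acc = (predict(model, val) == val.labels).mean()
        assert acc > 0.7

    def test_delay_zero_is_standard_recurrence(self, rng):
        train = separable_dataset(rng, 10, n_w=8)
        model = train_rnn(train, delay_s=0.0, epochs=2, seed=0)
        assert model.delay == 1

    def test_delay_seconds_mapped_to_steps(self, rng):
        train = separable_dataset(rng, 10, n_w=24)   # fs_power = 16
        model = train_rnn(train, delay_s=1.0, epochs=1, seed=0)
        assert model.delay == 16

    def test_excessive_delay_rejected(self, rng):
        train = separable_dataset(rng, 10, n_w=8)
        with pytest.raises(ValueError, match="delay"):
            train_rnn(train, delay_s=10.0, epochs=1)

    def test_deterministic(self, rng):
        train = separable_dataset(rng, 10, n_w=8)
        m1 = train_rnn(train, delay_s=0.25, epochs=3, seed=9)
        m2 = train_rnn(train, delay_s=0.25, epochs=3, seed=9)
        np.testing.assert_array_equal(m1.Wx, m2.Wx)


def blobs(rng, n=200, sep=6.0):
    X = np.vstack([rng.normal(0, 1, (n // 2, 2)),
                   rng.normal(sep, 1, (n // 2, 2))])
    y = np.array(["EO"] * (n // 2) + ["EC"] * (n // 2), dtype="<U2")
    return PointDataset(X, y)


class TestPointwise:
    def test_all_roster_options_fit_and_predict(self, rng):
        ds = blobs(rng, 240)
        from winbci.core_io import RunConfig

        for name in RunConfig().classifiers:
            clf = train_pointwise(ds, ClassifierSpec.parse(name), seed=0)
            labels = predict(clf, ds)
            assert set(labels) <= {"EO", "EC"}

    def test_1nn_memorizes_training_points(self, rng):
        ds = blobs(rng, 100, sep=2.0)
        clf = train_pointwise(ds, ClassifierSpec("KNN", "fine"), seed=0)
        assert (predict(clf, ds) == ds.labels).all()

    def test_linear_svm_separates_blobs(self, rng):
        train = blobs(rng, 200)
        val = blobs(np.random.default_rng(4), 100)
        clf = train_pointwise(train, ClassifierSpec("SVM", "linear"), seed=0)
        assert (predict(clf, val) == val.labels).mean() == 1.0

    def test_coarse_tree_at_least_matches_stump_on_xor(self, rng):
        centers = np.array([[0, 0], [4, 4], [0, 4], [4, 0]], float)
        X = np.vstack([c + rng.normal(0, 0.4, (50, 2)) for c in centers])
        y = np.array(["EO"] * 100 + ["EC"] * 100, dtype="<U2")
        ds = PointDataset(X, y)
        coarse = train_pointwise(ds, ClassifierSpec("DTL", "coarse"), seed=0)
        from sklearn.tree import DecisionTreeClassifier

        stump = DecisionTreeClassifier(max_leaf_nodes=2, random_state=0)
        stump.fit(X, y)
        acc_coarse = (predict(coarse, ds) == y).mean()
        acc_stump = (stump.predict(X) == y).mean()
        assert acc_coarse >= acc_stump

    def test_k_exceeding_training_size(self, rng):
        ds = blobs(rng, 40)
        with pytest.raises(ValueError, match="k=100"):
            train_pointwise(ds, ClassifierSpec("KNN", "coarse"), seed=0)

    def test_unknown_option_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ClassifierSpec("SVM", "quartic")


class TestPredictDispatch:
    def test_empty_inputs(self, rng):
        model = random_model(rng)
        out = predict(model, np.empty((0, 5, 2)))
        assert out.shape == (0,)

    def test_argmax_consistent_with_forward(self, rng):
        model = random_model(rng)
        ds = separable_dataset(rng, 10, n_w=6)
        labels = predict(model, ds)
        probs = lstm_forward(model, ds.sequences)
        expect = np.array(model.classes)[np.argmax(probs, axis=1)]
        np.testing.assert_array_equal(labels, expect)

    def test_unsupported_type(self):
        with pytest.raises(TypeError):
            predict(object(), np.zeros((1, 2)))
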