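import numpy as np
import pytest

from histofusion.ann import (
    MLPModel, ann_init, ann_predict, ann_train, cross_entropy_loss,
    error_histogram, mse_loss, one_hot, regression_r, _forward, _gradients,
)
from histofusion.types import FeatureMatrix


def two_cluster_data(n=60, d=6, seed=0, spread=4.0):
    """Separable five-cluster data; class centers are fixed across seeds."""
    labels = np.arange(n) % 5
    centers = np.random.default_rng(424242).standard_normal((5, d)) * spread
    X = centers[labels] + np.random.default_rng(seed).standard_normal((n, d))
    return FeatureMatrix(values=X, labels=labels, source_tag="toy")


class TestLosses:
    def test_mse_zero_on_identical(self):
        assert mse_loss([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_mse_direct_value(self):
        assert mse_loss([1.0, 0.0], [0.0, 0.0]) == pytest.approx(0.5)

    def test_mse_matches_loop_oracle(self, rng):
        a, e = rng.standard_normal(17), rng.standard_normal(17)
        expected = sum((x - y) ** 2 for x, y in zip(a, e)) / 17
        assert mse_loss(a, e) == pytest.approx(expected)

    def test_mse_length_mismatch(self):
        with pytest.raises(ValueError):
            mse_loss([1.0], [1.0, 2.0])

    def test_cross_entropy_perfect_prediction(self):
        y = one_hot(np.array([0, 1]), 2)
        assert cross_entropy_loss(y, y) == pytest.approx(0.0, abs=1e-9)


class TestGradients:
    @pytest.mark.parametrize("loss", ["mse", "cross_entropy"])
    def test_analytic_matches_finite_difference(self, loss, rng):
        """Central finite differences on a tiny network, tolerance 1e-5."""
        model = ann_init(3, hidden_units=4, output_units=5, seed=1, loss=loss)
        X = rng.standard_normal((7, 3))
        Y = one_hot(rng.integers(0, 5, 7), 5)
        _, grads = _gradients(model, X, Y)
        eps = 1e-6
        for name, grad in zip(("W1", "b1", "W2", "b2"), grads):
            param = getattr(model, name)
            it = np.nditer(param, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = param[idx]
                param[idx] = orig + eps
                _, Op = _forward(model, X)
                lp = cross_entropy_loss(Op, Y) if loss == "cross_entropy" else mse_loss(Op, Y)
                param[idx] = orig - eps
                _, Om = _forward(model, X)
                lm = cross_entropy_loss(Om, Y) if loss == "cross_entropy" else mse_loss(Om, Y)
                param[idx] = orig
                fd = (lp - lm) / (2 * eps)
                assert grad[idx] == pytest.approx(fd, abs=1e-5)


class TestTraining:
    def test_separable_data_high_training_accuracy(self):
        train = two_cluster_data(n=100, seed=0)
        val = two_cluster_data(n=50, seed=1)
        model = ann_init(train.dim, seed=0)
        model, hist = ann_train(model, train, val, max_epochs=200)
        _, pred = ann_predict(model, train)
        assert (pred == train.labels).mean() >= 0.99
        assert hist.train_loss[hist.best_epoch] <= hist.train_loss[0]

    def test_stops_after_max_fail_consecutive_failures(self):
        train = two_cluster_data(n=50, seed=2)
        # validation drawn from a different distribution so it degrades
        rng = np.random.default_rng(9)
        val = FeatureMatrix(values=rng.standard_normal((25, train.dim)) * 10,
                            labels=rng.integers(0, 5, 25), source_tag="val")
        model = ann_init(train.dim, seed=3)
        model, hist = ann_train(model, train, val, max_fail=6, max_epochs=500)
        if "validation failed" in hist.stop_reason:
            assert hist.validation_failures[-1] == 6
            assert hist.n_epochs == hist.best_epoch + 7  # 6 failures after best

    def test_zero_epoch_budget_returns_init_unchanged(self):
        train = two_cluster_data(n=20, seed=4)
        init = ann_init(train.dim, seed=5)
        model, hist = ann_train(init, train, train, max_epochs=0)
        assert hist.n_epochs == 0
        assert np.array_equal(model.W1, init.W1)

    def test_fixed_seed_bit_identical_runs(self):
        train = two_cluster_data(n=40, seed=6)
        val = two_cluster_data(n=20, seed=7)
        out = []
        for _ in range(2):
            m, h = ann_train(ann_init(train.dim, seed=11), train, val, max_epochs=50)
            out.append((m, h))
        assert np.array_equal(out[0][0].W1, out[1][0].W1)
        assert out[0][1].train_loss == out[1][1].train_loss

    def test_validation_failures_reset_on_improvement(self):
        train = two_cluster_data(n=60, seed=8)
        val = two_cluster_data(n=30, seed=9)
        _, hist = ann_train(ann_init(train.dim, seed=2), train, val, max_epochs=100)
        fails = hist.validation_failures
        for i in range(1, len(fails)):
            assert fails[i] in (0, fails[i - 1] + 1)

    def test_empty_validation_rejected(self):
        train = two_cluster_data(n=20, seed=1)
        empty = FeatureMatrix.__new__(FeatureMatrix)
        empty.values = np.zeros((0, train.dim))
        empty.labels = np.zeros(0, dtype=int)
        with pytest.raises(ValueError):
            ann_train(ann_init(train.dim), train, empty, max_epochs=5)


class TestPredict:
    def test_softmax_rows_sum_to_one(self):
        data = two_cluster_data(n=30, seed=3)
        model = ann_init(data.dim, seed=1)
        scores, _ = ann_predict(model, data)
        assert np.allclose(scores.sum(axis=1), 1.0)

    def test_zero_weight_model_uniform_scores(self):
        model = MLPModel(W1=np.zeros((4, 3)), b1=np.zeros(3),
                         W2=np.zeros((3, 5)), b2=np.zeros(5))
        scores, _ = ann_predict(model, np.ones((2, 4)))
        assert np.allclose(scores, 0.2)

    def test_argmax_labels_match_scores(self, rng):
        data = two_cluster_data(n=25, seed=5)
        model = ann_init(data.dim, seed=2)
        scores, pred = ann_predict(model, data)
        assert np.array_equal(pred, scores.argmax(axis=1))

    def test_dim_mismatch(self):
        model = ann_init(4)
        with pytest.raises(ValueError):
            ann_predict(model, np.ones((2, 5)))


class TestDiagnostics:
    def test_error_histogram_perfect_predictions(self):
        t = np.eye(5)[np.array([0, 1, 2])]
        edges, counts = error_histogram(t, t, n_bins=20)
        total = counts["all"].sum()
        zero_bin = np.searchsorted(edges, 0.0, side="right") - 1
        assert counts["all"][min(zero_bin, 19)] == total == 15

    def test_error_histogram_extreme_bins(self):
        t = np.array([0.0, 1.0])
        o = np.array([1.0, 0.0])  # errors -1 and +1
        edges, counts = error_histogram(t, o, n_bins=20)
        assert counts["all"][0] == 1 and counts["all"][-1] == 1

    def test_counts_sum_to_sample_output_pairs(self, rng):
        t = rng.standard_normal((13, 5))
        o = rng.standard_normal((13, 5))
        _, counts = error_histogram({"train": t}, {"train": o})
        assert counts["train"].sum() == 13 * 5

    def test_regression_r_perfect_and_anti(self, rng):
        t = rng.standard_normal(40)
        assert regression_r(t, t) == pytest.approx(100.0)
        assert regression_r(t, -t) == pytest.approx(-100.0)

    def test_regression_r_matches_covariance_formula(self, rng):
        t, o = rng.standard_normal(31), rng.standard_normal(31)
        r = ((t - t.mean()) * (o - o.mean())).mean() / (t.std() * o.std())
        assert regression_r(t, o) == pytest.approx(100 * r)

    def test_regression_r_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            regression_r(np.ones(5), np.arange(5.0))
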