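"""Linear SVM decoding: cross-validation, maximum-margin agreement with a
quadratic-program oracle, sleep voting and weight summaries."""

import numpy as np
import pytest
from scipy.optimize import minimize

from gammareplay import beta_by_area, crossvalidate, predict_sleep, train_full
from gammareplay.containers import TrialMatrix


def make_tm(features, labels, valid=None):
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    return TrialMatrix(
        features,
        np.asarray(labels, dtype=object),
        np.full(n, -1),
        np.ones(n, dtype=bool) if valid is None else np.asarray(valid, bool),
        "test",
        [f"c{i}" for i in range(features.shape[1])],
    )


def gaussian_problem(rng, n_per_class=100, sep=6.0, d=4):
    x1 = rng.standard_normal((n_per_class, d)) + sep / 2
    x0 = rng.standard_normal((n_per_class, d)) - sep / 2
    X = np.vstack([x1, x0])
    y = np.array(["motor"] * n_per_class + ["rest"] * n_per_class, dtype=object)
    return make_tm(X, y)


def test_separable_problem_high_da(rng):
    cv = crossvalidate(gaussian_problem(rng), seed=0)
    assert cv.decoding_accuracy >= 0.98
    assert len(cv.fold_accuracies) == 5


def test_shuffled_labels_at_chance(rng):
    tm = gaussian_problem(rng, n_per_class=100)
    das = []
    for seed in range(10):
        perm = np.random.default_rng(seed).permutation(tm.n_trials)
        shuffled = make_tm(tm.features, tm.labels[perm])
        # permutation may unbalance nothing: labels are a permutation
        das.append(crossvalidate(shuffled, seed=seed).decoding_accuracy)
    mean_da = np.mean(das)
    # binomial 95% band around 0.5 for 10 x 200 trials
    half = 1.96 * np.sqrt(0.25 / (10 * 200))
    assert abs(mean_da - 0.5) < half + 0.05


def test_cv_seed_reproducible(rng):
    tm = gaussian_problem(rng)
    a = crossvalidate(tm, seed=3)
    b = crossvalidate(tm, seed=3)
    assert np.array_equal(a.fold_accuracies, b.fold_accuracies)


def test_duplicating_trials_keeps_da(rng):
    tm = gaussian_problem(rng, n_per_class=50)
    dup = make_tm(
        np.vstack([tm.features, tm.features]),
        np.concatenate([tm.labels, tm.labels]),
    )
    assert crossvalidate(dup, seed=0).decoding_accuracy >= 0.98


def test_unbalanced_input_rejected(rng):
    x = rng.standard_normal((30, 2))
    y = np.array(["motor"] * 20 + ["rest"] * 10, dtype=object)
    with pytest.raises(ValueError, match="balance"):
        crossvalidate(make_tm(x, y))


def test_1d_toy_weights_positive():
    tm = make_tm([[1.0], [2.0], [-1.0], [-2.0]], ["motor", "motor", "rest", "rest"])
    model = train_full(tm)
    assert model.beta[0] > 0
    d = model.decision_values(tm.features)
    assert np.all(d[:2] > 0) and np.all(d[2:] < 0)


def test_sign_flip_symmetry():
    tm = make_tm([[1.0, 2.0], [2.0, 1.5], [-1.0, -2.0], [-2.0, -0.5]],
                 ["motor", "motor", "rest", "rest"])
    m1 = train_full(tm)
    tm2 = make_tm(-tm.features, tm.labels)
    m2 = train_full(tm2)
    assert np.allclose(m2.beta, -m1.beta, atol=1e-6)
    assert np.allclose(
        m1.decision_values(tm.features), m2.decision_values(-tm.features), atol=1e-6
    )


def hard_margin_oracle(X, y):
    """Brute-force maximum-margin separator: min 1/2 ||w||^2 s.t.
    y_i (w.x_i + b) >= 1, solved as a smooth constrained program."""
    d = X.shape[1]

    def obj(p):
        return 0.5 * np.dot(p[:d], p[:d])

    cons = [
        {"type": "ineq", "fun": lambda p, i=i: y[i] * (X[i] @ p[:d] + p[d]) - 1.0}
        for i in range(len(y))
    ]
    best = None
    for x0 in (np.r_[np.ones(d), 0.0], np.r_[-np.ones(d), 0.5]):
        res = minimize(obj, x0, constraints=cons, method="SLSQP",
                       options={"maxiter": 500, "ftol": 1e-12})
        if res.success and (best is None or res.fun < best.fun):
            best = res
    return best.x[:d], best.x[d]


def test_decision_values_match_qp_oracle():
    """Six hand-placed 2-D points, margin wide enough that the C=1
    soft-margin solution coincides with the hard-margin separator."""
    X = np.array([[2.0, 0.0], [3.0, 1.0], [3.0, -1.0],
                  [-2.0, 0.0], [-3.0, 1.0], [-3.0, -1.0]])
    labels = np.array(["motor"] * 3 + ["rest"] * 3, dtype=object)
    tm = make_tm(X, labels)
    model = train_full(tm)
    # oracle operates in the same standardized space as the model
    Xs = (X - model.mu) / model.sigma
    y = np.array([1, 1, 1, -1, -1, -1], dtype=float)
    w, b = hard_margin_oracle(Xs, y)
    d_model = model.decision_values(X)
    d_oracle = Xs @ w + b
    assert np.allclose(d_model, d_oracle, atol=1e-3)


def test_degenerate_features_rejected():
    tm = make_tm(np.ones((10, 2)), ["motor"] * 5 + ["rest"] * 5)
    with pytest.raises(ValueError):
        train_full(tm)


class TestPredictSleep:
    def _model(self, rng):
        return train_full(gaussian_problem(rng, n_per_class=50, d=3))

    def test_motor_centroid_votes_motor(self, rng):
        tm = gaussian_problem(rng, n_per_class=50, d=3)
        model = train_full(tm)
        centroid = tm.features[tm.labels == "motor"].mean(axis=0, keepdims=True)
        votes, _ = predict_sleep(model, make_tm(centroid, ["unlabeled"]))
        assert votes[0]

    def test_vote_matches_manual_decision_value(self, rng):
        model = self._model(rng)
        x = rng.standard_normal((1, 3))
        d_manual = float(((x[0] - model.mu) / model.sigma) @ model.beta + model.bias)
        votes, _ = predict_sleep(model, make_tm(x, ["unlabeled"]))
        assert votes[0] == (d_manual > 0)

    def test_empty_and_invalid_trials(self, rng):
        model = self._model(rng)
        votes, ids = predict_sleep(model, make_tm(np.empty((0, 3)), []))
        assert votes.size == 0 and ids.size == 0
        tm = make_tm(rng.standard_normal((4, 3)), ["unlabeled"] * 4,
                     valid=[True, False, True, False])
        votes, _ = predict_sleep(model, tm)
        assert len(votes) == 2

    def test_dimension_mismatch_error(self, rng):
        model = self._model(rng)
        with pytest.raises(ValueError, match="dimension"):
            predict_sleep(model, make_tm(rng.standard_normal((2, 5)), ["unlabeled"] * 2))


class TestBetaByArea:
    def _model_with_beta(self, beta):
        from gammareplay.containers import DecodingModel

        beta = np.asarray(beta, dtype=float)
        return DecodingModel(beta, 0.0, np.zeros_like(beta), np.ones_like(beta),
                             [f"c{i}" for i in range(len(beta))])

    def test_minmax_rescale(self):
        table = beta_by_area(self._model_with_beta([2.0, -4.0, 6.0]), ["a", "b", "c"])
        got = dict(zip(table["area"], table["rescaled_abs_beta"]))
        assert got == {"a": 0.0, "b": 0.5, "c": 1.0}

    def test_single_channel_convention(self):
        table = beta_by_area(self._model_with_beta([3.0]), ["a"])
        assert table["rescaled_abs_beta"].iloc[0] == 1.0

    def test_per_area_maximum(self):
        table = beta_by_area(self._model_with_beta([1.0, 2.0, 3.0]), ["a", "a", "b"])
        got = dict(zip(table["area"], table["rescaled_abs_beta"]))
        assert got["a"] == 0.5 and got["b"] == 1.0

    def test_unlabeled_channel_error(self):
        with pytest.raises(ValueError):
            beta_by_area(self._model_with_beta([1.0, 2.0]), ["a", ""])
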