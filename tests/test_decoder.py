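import numpy as np
import pytest
from scipy.optimize import minimize

from decnef.decoder import (
    DecoderModel,
    PlattScaledLinearSVM,
    assemble_training_set,
    decision_value,
    fit_platt,
    platt_probability,
    svm_primal_objective,
    train_linear_svm,
    train_run_decoder,
)
from decnef.preprocess import TrialFeature
from decnef.schedule import Condition


def svm_qp_oracle(X, y, C=1.0):
    """Primal soft-margin QP solved with SLSQP: independent of libsvm."""
    n, d = X.shape

    def objective(z):
        w, b, xi = z[:d], z[d], z[d + 1 :]
        return 0.5 * w @ w + C * xi.sum()

    constraints = [
        {
            "type": "ineq",
            "fun": lambda z, i=i: y[i] * (X[i] @ z[:d] + z[d]) - 1 + z[d + 1 + i],
        }
        for i in range(n)
    ]
    bounds = [(None, None)] * (d + 1) + [(0, None)] * n
    res = minimize(
        objective,
        np.zeros(d + 1 + n),
        method="SLSQP",
        bounds=bounds,
        constraints=constraints,
        options={"maxiter": 500, "ftol": 1e-12},
    )
    assert res.success
    return res.x[:d], res.x[d], res.fun


class TestTrainLinearSvm:
    def test_separable_1d_toy(self):
        X = np.array([[1.0], [-1.0]])
        y = np.array([1, -1])
        w, b = train_linear_svm(X, y)
        assert w[0] == pytest.approx(1.0, abs=1e-6)
        assert b == pytest.approx(0.0, abs=1e-6)

    def test_identical_points_opposite_labels_give_zero_weights(self):
        X = np.array([[0.5, -0.2], [0.5, -0.2]])
        y = np.array([1, -1])
        w, _ = train_linear_svm(X, y)
        assert np.allclose(w, 0.0, atol=1e-8)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_linear_svm(np.ones((4, 2)), np.ones(4, dtype=int))

    @pytest.mark.parametrize("seed", range(6))
    def test_objective_matches_qp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, d = rng.integers(8, 14), rng.integers(2, 4)
        y = np.array([1] * (n // 2) + [-1] * (n - n // 2))
        X = rng.normal(size=(n, d)) + 0.5 * y[:, None]
        w, b = train_linear_svm(X, y)
        _, _, f_oracle = svm_qp_oracle(X, y)
        f_impl = svm_primal_objective(w, b, X, y)
        assert f_impl == pytest.approx(f_oracle, abs=1e-6)

    def test_support_vector_margins_satisfy_kkt(self):
        # hard-margin separable: support vectors sit exactly at |f| = 1
        X = np.array([[2.0, 0.0], [0.0, 2.0], [-2.0, 0.0], [0.0, -2.0]])
        y = np.array([1, 1, -1, -1])
        w, b = train_linear_svm(X, y)
        margins = y * (X @ w + b)
        assert margins.min() == pytest.approx(1.0, abs=1e-6)


class TestDecisionValue:
    def test_zero_model_maps_everything_to_zero(self):
        m = DecoderModel(weights=np.zeros(3), bias=0.0, c_param=1.0, platt_a=-1.0, platt_b=0.0)
        assert m.decision_value(np.array([5.0, -2.0, 1.0])) == 0.0

    def test_linearity_without_bias(self, rng):
        w = rng.normal(size=4)
        m = DecoderModel(weights=w, bias=0.0, c_param=1.0, platt_a=-1.0, platt_b=0.0)
        x = rng.normal(size=4)
        assert m.decision_value(3.0 * x) == pytest.approx(3.0 * m.decision_value(x))

    def test_dimension_mismatch(self):
        m = DecoderModel(weights=np.ones(3), bias=0.0, c_param=1.0, platt_a=-1.0, platt_b=0.0)
        with pytest.raises(ValueError):
            m.decision_value(np.ones(4))


class TestFitPlatt:
    def test_symmetric_decisions_give_zero_intercept(self):
        f = np.array([-2.0, -1.0, 1.0, 2.0])
        y = np.array([-1, -1, 1, 1])
        a, b = fit_platt(f, y)
        assert b == pytest.approx(0.0, abs=1e-6)
        assert platt_probability(a, b, 0.0) == pytest.approx(0.5, abs=1e-9)

    def test_recovers_known_parameters(self):
        rng = np.random.default_rng(0)
        a_true, b_true = -2.0, 0.5
        f = rng.normal(0, 1.5, size=2000)
        p = 1.0 / (1.0 + np.exp(a_true * f + b_true))
        y = np.where(rng.random(2000) < p, 1, -1)
        a, b = fit_platt(f, y)
        assert a == pytest.approx(a_true, abs=0.15)
        assert b == pytest.approx(b_true, abs=0.15)

    def test_separable_data_stay_finite(self):
        f = np.array([-3.0, -2.0, 2.0, 3.0])
        y = np.array([-1, -1, 1, 1])
        a, b = fit_platt(f, y)
        assert np.isfinite(a) and np.isfinite(b)
        assert a < 0

    def test_matches_sklearn_sigmoid_calibration_oracle(self):
        from sklearn.calibration import _sigmoid_calibration

        rng = np.random.default_rng(3)
        f = rng.normal(size=400)
        y = np.where(rng.random(400) < 1.0 / (1.0 + np.exp(-1.5 * f + 0.3)), 1, -1)
        a, b = fit_platt(f, y)
        # sklearn parameterises P = 1/(1+exp(A*f + B)) on y in {0,1}
        a_sk, b_sk = _sigmoid_calibration(f, (y == 1).astype(float))
        assert a == pytest.approx(float(a_sk), abs=1e-3)
        assert b == pytest.approx(float(b_sk), abs=1e-3)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_platt([0.1, 0.2], [1, 1])

    def test_orientation_constraint_keeps_a_nonpositive(self):
        # anti-informative decisions: unconstrained MLE would give A > 0
        f = np.array([2.0, 1.0, -1.0, -2.0])
        y = np.array([-1, -1, 1, 1])
        a, _ = fit_platt(f, y)
        assert a <= 0.0


def _features(run_index, n=24, dim=6, seed=0):
    rng = np.random.default_rng(seed + run_index)
    out = []
    for i in range(n):
        label = Condition.INTEROCEPTIVE if i % 2 == 0 else Condition.EXTEROCEPTIVE
        sign = 1.0 if label is Condition.INTEROCEPTIVE else -1.0
        out.append(
            TrialFeature(
                values=rng.normal(size=dim) + 2.0 * sign,
                label=label,
                run_index=run_index,
                trial_index=i,
            )
        )
    return out


class TestAssembleTrainingSet:
    def test_run1_uses_decoder_task_only(self):
        history = {0: _features(0)}
        assert len(assemble_training_set(history, 1)) == 24

    def test_run3_pools_72_trials_in_chronological_order(self):
        history = {r: _features(r) for r in range(3)}
        trials = assemble_training_set(history, 3)
        assert len(trials) == 72
        assert [t.run_index for t in trials] == [0] * 24 + [1] * 24 + [2] * 24

    def test_missing_history_raises(self):
        with pytest.raises(ValueError, match="missing"):
            assemble_training_set({0: _features(0)}, 3)

    def test_invalid_target_run(self):
        with pytest.raises(ValueError):
            assemble_training_set({0: _features(0)}, 0)


class TestTrainRunDecoder:
    def test_provenance_recorded(self):
        model = train_run_decoder({0: _features(0)}, 1)
        assert model.trained_on_runs == [0]
        model3 = train_run_decoder({r: _features(r) for r in range(3)}, 3)
        assert model3.trained_on_runs == [0, 1, 2]

    def test_training_accuracy_perfect_on_separable_data(self):
        history = {0: _features(0)}
        model = train_run_decoder(history, 1)
        signs = [np.sign(model.decision_value(f)) for f in history[0]]
        truth = [1.0 if f.label is Condition.INTEROCEPTIVE else -1.0 for f in history[0]]
        assert signs == truth

    def test_platt_parameters_change_when_data_added(self):
        h2 = {0: _features(0), 1: _features(1)}
        h3 = {**h2, 2: _features(2)}
        m2 = train_run_decoder(h2, 2)
        m3 = train_run_decoder(h3, 3)
        assert (m2.platt_a, m2.platt_b) != (m3.platt_a, m3.platt_b)

    def test_json_round_trip(self, tmp_path):
        model = train_run_decoder({0: _features(0)}, 1)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = DecoderModel.from_json(path)
        assert np.allclose(back.weights, model.weights)
        assert back.platt_a == model.platt_a
        assert back.trained_on_runs == model.trained_on_runs


class TestEstimatorInterface:
    def test_sklearn_clone_and_params(self):
        from sklearn.base import clone

        est = PlattScaledLinearSVM(C=2.0)
        assert clone(est).get_params()["C"] == 2.0

    def test_predict_proba_columns_sum_to_one(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.where(X[:, 0] + 0.3 * rng.normal(size=30) > 0, 1, -1)
        if len(np.unique(y)) == 1:
            y[0] = -y[0]
        est = PlattScaledLinearSVM().fit(X, y)
        proba = est.predict_proba(X)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert est.platt_a_ <= 0

    def test_probability_calibration_reliability(self):
        # binned mean predicted P tracks empirical frequency; slope near 1
        rng = np.random.default_rng(11)
        n = 2000
        X = rng.normal(size=(n, 2))
        latent = X[:, 0]
        y = np.where(rng.random(n) < 1.0 / (1.0 + np.exp(-1.2 * latent)), 1, -1)
        est = PlattScaledLinearSVM().fit(X, y)
        p = est.predict_proba(X)[:, 1]
        bins = np.clip((p * 10).astype(int), 0, 9)
        pred, obs = [], []
        for k in range(10):
            m = bins == k
            if m.sum() >= 30:
                pred.append(p[m].mean())
                obs.append((y[m] == 1).mean())
        slope = np.polyfit(pred, obs, 1)[0]
        assert 0.8 <= slope <= 1.2


def test_decision_value_wrapper_matches_method(rng):
    m = DecoderModel(weights=rng.normal(size=5), bias=0.3, c_param=1.0, platt_a=-1.0, platt_b=0.1)
    x = rng.normal(size=5)
    assert decision_value(m, x) == m.decision_value(x)
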