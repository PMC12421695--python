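"""Linear attention-state decoder with per-run Platt probability calibration.

The decoder is a soft-margin linear SVM (C = 1) on spatiotemporal trial
features, whose decision value f(x) = w.x + b is mapped to a probability
of the interoceptive state through Platt scaling

    P(y = 1 | x) = 1 / (1 + exp(A_r f(x) + B_r)),

with (A_r, B_r) re-estimated before each regulation run r on all data the
decoder has been trained on so far.  Before run 1 only the decoder-training
task is available; before runs 2 and 3 the previous regulation runs are
appended in chronological order (incremental retraining).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC

from .preprocess import TrialFeature, feature_matrix

__all__ = [
    "DecoderModel",
    "PlattScaledLinearSVM",
    "train_linear_svm",
    "decision_value",
    "fit_platt",
    "assemble_training_set",
    "train_run_decoder",
    "svm_primal_objective",
]


def train_linear_svm(
    X: np.ndarray, y: np.ndarray, c_param: float = 1.0, tol: float = 1e-8
) -> Tuple[np.ndarray, float]:
    """Fit the soft-margin linear SVM and return (weights, bias).

    Minimises (1/2)||w||^2 + C * sum_i hinge(y_i (w.x_i + b)); label +1 is
    the interoceptive state.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if c_param <= 0:
        raise ValueError("c_param must be positive")
    clf = SVC(kernel="linear", C=c_param, tol=tol)
    clf.fit(X, y)
    w = clf.coef_.ravel().copy()
    b = float(clf.intercept_[0])
    return w, b


def svm_primal_objective(
    w: np.ndarray, b: float, X: np.ndarray, y: np.ndarray, c_param: float = 1.0
) -> float:
    """Soft-margin primal objective (1/2)||w||^2 + C sum hinge."""
    margins = y * (X @ w + b)
    return 0.5 * float(w @ w) + c_param * float(np.maximum(0.0, 1.0 - margins).sum())


def fit_platt(decisions: Sequence[float], labels: Sequence[int]) -> Tuple[float, float]:
    """Maximum-likelihood Platt parameters (A, B) with regularised targets.

    Fits P(y=1|f) = 1 / (1 + exp(A f + B)) by minimising the cross-entropy
    against Platt's smoothed targets t+ = (N+ + 1)/(N+ + 2) and
    t- = 1/(N- + 2), which keep (A, B) finite on separable data.  A is
    constrained non-positive so that larger decision values always mean a
    larger interoceptive probability.
    """
    f = np.asarray(decisions, dtype=float)
    y = np.asarray(labels, dtype=int)
    if f.shape != y.shape:
        raise ValueError("decisions and labels must align")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == -1))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll_and_grad(theta: np.ndarray) -> Tuple[float, np.ndarray]:
        a, b = theta
        z = a * f + b
        # log(1 + e^z) computed stably; p = sigma(-z)
        log1pez = np.logaddexp(0.0, z)
        nll = float(np.sum(t * log1pez + (1.0 - t) * np.logaddexp(0.0, -z)))
        p = 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))
        dz = t - p  # d(nll)/dz with p = P(y=1|f) = sigma(-z)
        return nll, np.array([np.sum(dz * f), np.sum(dz)])

    res = minimize(
        nll_and_grad,
        x0=np.array([-1.0, 0.0]),
        jac=True,
        method="L-BFGS-B",
        bounds=[(None, 0.0), (None, None)],
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-10},
    )
    a, b = res.x
    return float(a), float(b)


def platt_probability(a: float, b: float, decision: np.ndarray | float) -> np.ndarray | float:
    z = np.clip(a * np.asarray(decision, dtype=float) + b, -500, 500)
    return 1.0 / (1.0 + np.exp(z))


class PlattScaledLinearSVM(BaseEstimator, ClassifierMixin):
    """Linear SVM with Platt-scaled probabilities, sklearn-compatible.

    Parameters
    ----------
    C : float
        Soft-margin regularisation constant.
    tol : float
        Optimiser convergence tolerance of the underlying solver.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Weight vector w.
    intercept_ : float
        Bias b.
    platt_a_, platt_b_ : float
        Calibration parameters of ``P(y=1|x) = 1/(1+exp(A f(x) + B))``.
    classes_ : ndarray
        Always ``[-1, 1]``; +1 denotes the interoceptive state.
    """

    def __init__(self, C: float = 1.0, tol: float = 1e-8):
        self.C = C
        self.tol = tol

    def fit(self, X: np.ndarray, y: np.ndarray) -> "PlattScaledLinearSVM":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        if not set(np.unique(y)) <= {-1, 1}:
            raise ValueError("labels must be +/-1")
        w, b = train_linear_svm(X, y, c_param=self.C, tol=self.tol)
        self.coef_ = w
        self.intercept_ = b
        self.classes_ = np.array([-1, 1])
        self.platt_a_, self.platt_b_ = fit_platt(X @ w + b, y)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.coef_.shape[0]:
            raise ValueError("feature dimension mismatch")
        return X @ self.coef_ + self.intercept_

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p1 = platt_probability(self.platt_a_, self.platt_b_, self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0, 1, -1)


@dataclass
class DecoderModel:
    """Trained decoder state used during one regulation run.

    Carries the linear weights/bias, the run's Platt parameters and the
    indices of the runs whose trials entered training (provenance).
    """

    weights: np.ndarray
    bias: float
    c_param: float
    platt_a: float
    platt_b: float
    trained_on_runs: List[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if self.c_param <= 0:
            raise ValueError("c_param must be positive")
        if not (np.isfinite(self.platt_a) and np.isfinite(self.platt_b)):
            raise ValueError("Platt parameters must be finite")

    def decision_value(self, feature: TrialFeature | np.ndarray) -> float:
        x = feature.values if isinstance(feature, TrialFeature) else np.asarray(feature, float)
        if x.shape[0] != self.weights.shape[0]:
            raise ValueError(
                f"feature length {x.shape[0]} does not match weights {self.weights.shape[0]}"
            )
        return float(self.weights @ x + self.bias)

    def probability(self, feature: TrialFeature | np.ndarray) -> float:
        return float(platt_probability(self.platt_a, self.platt_b, self.decision_value(feature)))

    def to_dict(self) -> Dict:
        return {
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "c_param": self.c_param,
            "platt_a": self.platt_a,
            "platt_b": self.platt_b,
            "trained_on_runs": list(self.trained_on_runs),
        }

    @classmethod
    def from_dict(cls, d: Dict) -> "DecoderModel":
        return cls(
            weights=np.asarray(d["weights"], dtype=float),
            bias=float(d["bias"]),
            c_param=float(d["c_param"]),
            platt_a=float(d["platt_a"]),
            platt_b=float(d["platt_b"]),
            trained_on_runs=list(d["trained_on_runs"]),
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "DecoderModel":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def decision_value(model: DecoderModel, feature: TrialFeature | np.ndarray) -> float:
    """Signed distance from the decision boundary, f(x) = w.x + b."""
    return model.decision_value(feature)


def assemble_training_set(
    history: Dict[int, List[TrialFeature]], target_run: int
) -> List[TrialFeature]:
    """Training trials for the decoder of regulation run ``target_run``.

    Run 1 uses the decoder-training task only (run 0); runs 2 and 3 append
    the completed regulation runs 1..target_run-1 in chronological order.
    """
    if target_run not in (1, 2, 3):
        raise ValueError("target_run must be 1, 2 or 3")
    needed = [0] + list(range(1, target_run))
    missing = [r for r in needed if r not in history]
    if missing:
        raise ValueError(f"missing history for run(s) {missing}")
    out: List[TrialFeature] = []
    for r in needed:
        out.extend(history[r])
    return out


def train_run_decoder(
    history: Dict[int, List[TrialFeature]], target_run: int, c_param: float = 1.0
) -> DecoderModel:
    """Train SVM + Platt calibration on the assembled history for one run."""
    trials = assemble_training_set(history, target_run)
    X, y = feature_matrix(trials)
    est = PlattScaledLinearSVM(C=c_param).fit(X, y)
    return DecoderModel(
        weights=est.coef_,
        bias=est.intercept_,
        c_param=c_param,
        platt_a=est.platt_a_,
        platt_b=est.platt_b_,
        trained_on_runs=[0] + list(range(1, target_run)),
    )
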