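"""Offline trial-wise beta-series estimation and two-fold decoding accuracy.

Each run's 24 attention periods are modelled as individual 10-s boxcar
regressors convolved with the canonical double-gamma haemodynamic response
function (least-squares-all), with intercept and linear-drift nuisance
columns; rest, rating and feedback phases stay unmodelled and act as the
implicit baseline.  The resulting trials x voxels beta matrix feeds a
linear SVM (C = 1) evaluated with a deterministic class-balanced two-fold
cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .schedule import AcquisitionParams, Condition, RunSchedule


def canonical_hrf(tr_seconds: float, *, length_seconds: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at the TR, peak-normalised to 1.

    Peak gamma: delay 6 s, dispersion 1 s; undershoot gamma: delay 16 s,
    dispersion 1 s, weighted 1/6.  The kernel covers ``length_seconds``.
    """
    from scipy.stats import gamma

    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    t = np.arange(0.0, length_seconds + 1e-9, tr_seconds)
    peak = gamma.pdf(t, a=6.0, scale=1.0)
    undershoot = gamma.pdf(t, a=16.0, scale=1.0)
    h = peak - undershoot / 6.0
    return h / h.max()


@dataclass
class DesignMatrix:
    """Volumes x regressors GLM design with named columns."""

    matrix: np.ndarray
    names: List[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("column count does not match names")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def n_trial_columns(self) -> int:
        return sum(n.startswith("trial_") for n in self.names)


@dataclass
class BetaSeries:
    """Per-trial GLM coefficients (trials x voxels) with condition labels."""

    betas: np.ndarray
    labels: List[Condition]
    run_index: int

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.shape[0] != len(self.labels):
            raise ValueError("one label per trial required")
        if not np.all(np.isfinite(self.betas)):
            raise ValueError("betas contain non-finite values")


def _boxcar(n_volumes: int, onset_s: float, duration_s: float, tr: float) -> np.ndarray:
    grid = np.arange(n_volumes) * tr
    return ((grid >= onset_s - 1e-9) & (grid < onset_s + duration_s - 1e-9)).astype(float)


def dct_highpass_basis(n_volumes: int, tr_seconds: float, cutoff_seconds: float = 128.0) -> np.ndarray:
    """Discrete-cosine drift basis for a high-pass cutoff (SPM convention).

    Returns the K = floor(2 T / cutoff) lowest-frequency cosine regressors
    (the constant term excluded), where T is the run duration.
    """
    T = n_volumes * tr_seconds
    k_max = int(2.0 * T / cutoff_seconds)
    t = np.arange(n_volumes)
    basis = [
        np.cos(np.pi * k * (2 * t + 1) / (2 * n_volumes)) for k in range(1, k_max + 1)
    ]
    return np.column_stack(basis) if basis else np.empty((n_volumes, 0))


def build_beta_series_design(
    schedule: RunSchedule,
    n_volumes: Optional[int] = None,
    params: Optional[AcquisitionParams] = None,
    motion: Optional[np.ndarray] = None,
    drift_model: str = "cosine",
    highpass_cutoff_seconds: float = 128.0,
) -> DesignMatrix:
    """Least-squares-all design: one HRF-convolved boxcar per trial.

    Adds an intercept plus low-frequency nuisance regressors — by default
    a discrete-cosine high-pass set with a 128-s cutoff, which absorbs
    scanner drift so it cannot leak into the trial betas; ``drift_model =
    "linear"`` substitutes a single linear trend column.  Optional motion
    columns are appended as supplied (they are zero for synthetic data and
    hence omitted by default).
    """
    if params is None:
        params = AcquisitionParams()
    if n_volumes is None:
        n_volumes = schedule.n_volumes
    tr = params.tr_seconds
    hrf = canonical_hrf(tr)

    cols, names = [], []
    for block in schedule.blocks:
        box = _boxcar(n_volumes, block.regulation_onset_seconds, block.regulation_seconds, tr)
        if not box.any():
            raise ValueError(f"trial {block.block_index} lies outside the run")
        cols.append(np.convolve(box, hrf)[:n_volumes])
        names.append(f"trial_{block.block_index:02d}")
    cols.append(np.ones(n_volumes))
    names.append("intercept")
    if drift_model == "linear":
        cols.append(np.linspace(-1.0, 1.0, n_volumes))
        names.append("drift")
    elif drift_model == "cosine":
        basis = dct_highpass_basis(n_volumes, tr, highpass_cutoff_seconds)
        for j in range(basis.shape[1]):
            cols.append(basis[:, j])
            names.append(f"cosine_{j + 1:02d}")
    else:
        raise ValueError("drift_model must be 'cosine' or 'linear'")
    if motion is not None:
        motion = np.atleast_2d(np.asarray(motion, dtype=float))
        if motion.shape[0] != n_volumes:
            raise ValueError("motion regressors must have one row per volume")
        for j in range(motion.shape[1]):
            cols.append(motion[:, j])
            names.append(f"motion_{j}")
    return DesignMatrix(matrix=np.column_stack(cols), names=names)


def estimate_trial_betas(psc: np.ndarray, design: DesignMatrix, schedule: RunSchedule) -> BetaSeries:
    """Ordinary-least-squares fit per voxel; returns the trial coefficients."""
    psc = np.asarray(psc, dtype=float)
    if psc.shape[0] != design.matrix.shape[0]:
        raise ValueError("data and design row counts differ")
    coefs, *_ = np.linalg.lstsq(design.matrix, psc, rcond=None)
    n_trials = design.n_trial_columns
    return BetaSeries(
        betas=coefs[:n_trials],
        labels=[b.condition for b in schedule.blocks],
        run_index=schedule.run_index,
    )


def two_fold_cv_accuracy(
    betas: BetaSeries, seed: Optional[int] = None, c_param: float = 1.0
) -> float:
    """Two-fold cross-validated linear-SVM accuracy on a beta series.

    Folds are the two contiguous halves of the run (first 12 vs last 12
    trials), which condition alternation makes class-balanced (6 + 6 per
    fold).  Contiguous folds avoid interleaving train and test trials in
    time, so residual slow nuisance cannot anti-generalise across folds.
    When ``seed`` is given, trials are instead permuted within condition
    before the split, exploring random balanced folds.
    """
    from sklearn.svm import SVC

    labels = np.array([1 if c is Condition.INTEROCEPTIVE else -1 for c in betas.labels])
    if len(np.unique(labels)) < 2:
        raise ValueError("both conditions required")
    counts = np.bincount((labels + 1) // 2, minlength=2)
    if counts[0] != counts[1]:
        raise ValueError("balanced labels required for two-fold CV")

    n = len(labels)
    order = np.arange(n)
    if seed is not None:
        rng = np.random.default_rng(seed)
        for lab in (-1, 1):
            idx = np.where(labels == lab)[0]
            order[idx] = rng.permutation(idx)
    # fold of the trial at position order[i] is i // (n/2): contiguous halves
    folds = np.empty(n, dtype=int)
    folds[order] = (np.arange(n) >= n // 2).astype(int)
    for f in (0, 1):
        if np.sum(labels[folds == f] == 1) != np.sum(labels[folds == f] == -1):
            raise ValueError("folds are not class-balanced")

    X = betas.betas
    accs = []
    for test_fold in (0, 1):
        train = folds != test_fold
        clf = SVC(kernel="linear", C=c_param)
        clf.fit(X[train], labels[train])
        accs.append(float(np.mean(clf.predict(X[~train]) == labels[~train])))
    return float(np.mean(accs))


def run_offline_cv(
    psc: np.ndarray,
    schedule: RunSchedule,
    params: Optional[AcquisitionParams] = None,
    seed: Optional[int] = None,
) -> float:
    """Convenience composition: design -> betas -> two-fold CV accuracy."""
    design = build_beta_series_design(schedule, psc.shape[0], params)
    betas = estimate_trial_betas(psc, design, schedule)
    return two_fold_cv_accuracy(betas, seed=seed)
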