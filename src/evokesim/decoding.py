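"""Time-resolved linear decoding and temporal generalisation matrices.

One linear discriminant analysis (LDA) decoder is trained per time point on
the channel values at that sample and tested, under stratified K-fold
cross-validation, at every time point of the trial. Entry (t, t') of the
resulting T x T temporal generalisation matrix (TGM) is the proportion of
held-out trials classified correctly by the decoder trained at t and tested
at t', averaged over folds. The diagonal is the standard time-point-wise
cross-validated accuracy; with two balanced classes, chance is 0.5.

LDA uses the least-squares solver with Ledoit-Wolf shrinkage of the shared
covariance toward the scaled identity, which keeps the fit well-conditioned
when per-fold trial counts are small relative to the channel count.
Per-time-point standardisation statistics are computed on the training trials
of each fold only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .simulator import EpochedData

__all__ = ["TGM", "fit_lda", "compute_tgm", "average_tgms"]


@dataclass
class TGM:
    """Temporal generalisation matrix.

    `accuracy[t, tp]` is the cross-validated proportion correct of the model
    trained at time t and tested at time tp; not symmetric in general.
    """

    accuracy: np.ndarray
    n_folds: int
    n_trials: int

    def __post_init__(self) -> None:
        acc = np.asarray(self.accuracy, dtype=float)
        if acc.ndim != 2 or acc.shape[0] != acc.shape[1]:
            raise ValueError("accuracy must be a square matrix")
        self.accuracy = acc

    @property
    def T(self) -> int:
        return self.accuracy.shape[0]

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.accuracy)


def fit_lda(X: np.ndarray, y: np.ndarray) -> LinearDiscriminantAnalysis:
    """Fit a shrinkage-LDA decoder on one time point's features.

    `X` is trials x channels, `y` the condition labels. Raises on a
    single-class fold.
    """
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("need at least two classes to fit a discriminant")
    clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    clf.fit(X, y)
    return clf


def compute_tgm(
    data: EpochedData | np.ndarray,
    labels: np.ndarray | None = None,
    n_folds: int = 10,
    seed: int = 0,
    standardise: bool = True,
    _leak_train: bool = False,
) -> TGM:
    """Cross-validated T x T temporal generalisation matrix.

    Stratified K-fold over trials; per fold, decoders are trained at every
    time point and tested at every time point on the held-out trials, and
    fold accuracies are averaged. `_leak_train` deliberately fits on all
    trials (a train/test-leak control used in regression tests); never use
    it for analysis.
    """
    if isinstance(data, EpochedData):
        X, y = data.data, data.labels
    else:
        X, y = np.asarray(data), None
    if labels is not None:
        y = np.asarray(labels)
    if y is None:
        raise ValueError("labels are required when passing a bare array")
    N, T, C = X.shape
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    classes, y_idx = np.unique(y, return_inverse=True)
    if classes.size != 2:
        raise ValueError("TGM decoding is defined here for exactly two classes")

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    acc = np.zeros((T, T))
    for train_idx, test_idx in skf.split(np.zeros(N), y_idx):
        if _leak_train:
            train_idx = np.arange(N)
        Xtr, Xte = X[train_idx], X[test_idx]
        ytr, yte = y_idx[train_idx], y_idx[test_idx]
        if np.unique(ytr).size < 2 or np.unique(yte).size < 2:
            raise ValueError("a fold is missing one of the classes")
        if standardise:
            mu = Xtr.mean(axis=0, keepdims=True)
            sd = Xtr.std(axis=0, keepdims=True)
            sd[sd < 1e-12] = 1.0
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
        coefs = np.empty((T, C))
        icepts = np.empty(T)
        for t in range(T):
            clf = fit_lda(Xtr[:, t, :], ytr)
            coefs[t] = clf.coef_[0]
            icepts[t] = clf.intercept_[0]
        # scores: (n_test * T_test, T_train) in one matmul per fold
        scores = Xte.reshape(-1, C) @ coefs.T + icepts
        preds = (scores > 0).reshape(len(test_idx), T, T)
        correct = preds == (yte[:, None, None] == 1)
        # axis order: (trial, test time, train time) -> accumulate (train, test)
        acc += correct.mean(axis=0).T
    acc /= n_folds
    return TGM(accuracy=acc, n_folds=n_folds, n_trials=N)


def average_tgms(tgms: list[TGM]) -> TGM:
    """Entrywise mean of TGMs of equal shape (e.g. across simulation runs)."""
    if not tgms:
        raise ValueError("need at least one TGM")
    shapes = {t.accuracy.shape for t in tgms}
    if len(shapes) != 1:
        raise ValueError(f"TGM shapes differ: {sorted(shapes)}")
    mean = np.mean([t.accuracy for t in tgms], axis=0)
    return TGM(accuracy=mean, n_folds=tgms[0].n_folds,
               n_trials=tgms[0].n_trials)
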