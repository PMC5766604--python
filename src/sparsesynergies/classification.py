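"""Benchmark head: regularized linear multi-class classifier and selection.

Action representations (coefficient matrices U) are scored by a ridge
regression onto one-hot class indicators — predictions are the argmax of
the class scores.  Hyperparameters of both the representation and the
classifier are chosen on noisy validation coefficients by stratified
5-fold cross-validation; the single test evaluation uses the winning
configuration.  Accuracies are finally standardized per subject
(t-score: subtract the subject's pooled mean, divide by the pooled SD)
so subjects with different base rates can be averaged.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold

from .decomposition import make_learner
from .preprocessing import KinematicDataset, SplitIndices, add_noise

LAMBDA_RM_GRID = [10.0 ** e for e in range(-20, 2)]  # log10 in [-20 .. 1]


class RidgeMulticlass(ClassifierMixin, BaseEstimator):
    """Ridge regression onto one-hot class indicators, argmax prediction.

    The intercept row is unpenalized; ties in the class scores break to
    the lowest class index for determinism.
    """

    def __init__(self, alpha=1e-3):
        self.alpha = alpha

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need >= 2 classes to fit a classifier")
        n, r = X.shape
        Y = (y[:, None] == self.classes_[None, :]).astype(float)
        Z = np.column_stack([np.ones(n), X])
        penalty = self.alpha * np.eye(r + 1)
        penalty[0, 0] = 0.0  # intercept unpenalized
        W = np.linalg.solve(Z.T @ Z + penalty, Z.T @ Y)
        self.intercept_ = W[0]
        self.coef_ = W[1:].T
        self.n_features_in_ = r
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; model expects {self.n_features_in_}"
            )
        return X @ self.coef_.T + self.intercept_

    def predict(self, X):
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]


def fit_ridge_multiclass(U, labels, lambda_rm: float) -> RidgeMulticlass:
    """Closed-form one-hot ridge fit (thin wrapper over the estimator)."""
    return RidgeMulticlass(alpha=lambda_rm).fit(U, labels)


def crossval_accuracy(U, labels, lambda_rm: float, k: int = 5,
                      seed: int = 0) -> float:
    """Mean fraction-correct over stratified k folds."""
    U = np.asarray(U, dtype=float)
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} rows; need >= k = {k} for "
            "stratified cross-validation"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(U, labels):
        model = RidgeMulticlass(alpha=lambda_rm).fit(U[tr], labels[tr])
        accs.append(float(np.mean(model.predict(U[te]) == labels[te])))
    return float(np.mean(accs))


@dataclass
class EvaluationRecord:
    """One benchmark outcome: subject x method x noise level."""

    subject_id: int | str
    method: str
    r: int
    lambda_: float
    eta: float
    sigma: float
    lambda_rm: float
    accuracy: float
    tscore: float = np.nan
    val_accuracy: float = np.nan
    problem: str = "all"


@dataclass
class HyperGrids:
    """Hyperparameter grids searched on the validation set."""

    r: list[int] = field(default_factory=lambda: [4, 8, 12, 16, 20, 24])
    lambda_: list[float] = field(default_factory=lambda: [1e-4, 1e-3, 1e-2, 1e-1, 1.0])
    eta: list[float] = field(default_factory=lambda: [1e-4, 1e-3, 1e-2, 1e-1, 1.0])
    lambda_rm: list[float] = field(default_factory=lambda: list(LAMBDA_RM_GRID))

    def method_grid(self, method: str):
        """(r, lambda_, eta) combinations relevant to one method."""
        if method == "pca":
            return [(r, 0.0, 0.0) for r in self.r]
        if method == "l1":
            return [(r, 0.0, e) for r, e in itertools.product(self.r, self.eta)]
        if method == "sspca":
            return [(r, l, 0.0) for r, l in itertools.product(self.r, self.lambda_)]
        if method == "srssd":
            return [(r, l, e) for r, l, e in
                    itertools.product(self.r, self.lambda_, self.eta)]
        raise ValueError(f"unknown method {method!r}")


def select_and_test(
    dataset: KinematicDataset,
    split: SplitIndices,
    method: str,
    grids: HyperGrids,
    sigma: float,
    seed: int,
    subject_id: int | str = 0,
    learner_opts: dict | None = None,
) -> tuple[EvaluationRecord, dict]:
    """Grid-search on noisy validation, single evaluation on noisy test.

    For each representation configuration: learn the dictionary on clean
    training rows, encode the noisy validation rows with it frozen, and
    score every classifier regularization by stratified 5-fold CV on the
    validation coefficients.  The winning configuration is refit on all
    validation coefficients and evaluated once on the noisy test rows.

    Returns the record plus an artifacts dict (winning learner, encoded
    train/test coefficients) for downstream metric computation.
    """
    combos = grids.method_grid(method)
    if not combos or not grids.lambda_rm:
        raise ValueError("empty hyperparameter grid")
    learner_opts = learner_opts or {}

    X_tr = dataset.X[split.train]
    y_val = dataset.labels[split.validation]
    y_te = dataset.labels[split.test]
    # noise seeds fixed per evaluation so every configuration sees the
    # same corrupted copies
    X_val = add_noise(dataset.X[split.validation], sigma, seed=seed * 7919 + 1)
    X_te = add_noise(dataset.X[split.test], sigma, seed=seed * 7919 + 2)

    best = None
    for r, lam, eta in combos:
        learner = make_learner(method, n_atoms=r, lambda_=lam, eta=eta,
                               n_sensors=dataset.s, random_state=seed,
                               **learner_opts)
        learner.fit(X_tr)
        U_val = learner.transform(X_val)
        for lam_rm in grids.lambda_rm:
            acc = crossval_accuracy(U_val, y_val, lam_rm, k=5, seed=seed)
            if best is None or acc > best["val_accuracy"]:
                best = dict(r=r, lambda_=lam, eta=eta, lambda_rm=lam_rm,
                            val_accuracy=acc, learner=learner, U_val=U_val)

    model = RidgeMulticlass(alpha=best["lambda_rm"]).fit(best["U_val"], y_val)
    U_te = best["learner"].transform(X_te)
    accuracy = float(np.mean(model.predict(U_te) == y_te))

    record = EvaluationRecord(
        subject_id=subject_id, method=method, r=best["r"],
        lambda_=best["lambda_"], eta=best["eta"], sigma=sigma,
        lambda_rm=best["lambda_rm"], accuracy=accuracy,
        val_accuracy=best["val_accuracy"],
    )
    artifacts = dict(learner=best["learner"], classifier=model,
                     U_val=best["U_val"], U_test=U_te,
                     y_val=y_val, y_test=y_te)
    return record, artifacts


def tscore_normalize(records: list[EvaluationRecord]) -> list[EvaluationRecord]:
    """Standardize accuracies within each subject's pooled distribution.

    tscore = (accuracy - subject mean) / subject SD with the n-1
    denominator, pooling all of the subject's records (all methods, noise
    levels and problems).  Mutates and returns the records.
    """
    by_subject: dict = {}
    for rec in records:
        by_subject.setdefault(rec.subject_id, []).append(rec)
    for subject, recs in by_subject.items():
        accs = np.array([r.accuracy for r in recs], dtype=float)
        if accs.size < 2:
            raise ValueError(f"subject {subject!r} has < 2 records")
        sd = accs.std(ddof=1)
        if sd == 0:
            raise ValueError(
                f"subject {subject!r} has zero accuracy spread; t-score undefined"
            )
        mean = accs.mean()
        for r in recs:
            r.tscore = float((r.accuracy - mean) / sd)
    return records
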