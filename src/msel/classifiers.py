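"""Per-source base classifiers and their evaluation protocol.

Each individual source model is trained on the incomplete-data subjects
contributing that source.  The protocol: the training pool is balanced to
equal case/control counts by random undersampling, split with repeated
stratified k-fold cross-validation, and normalized to zero mean / unit
variance using statistics of the training rows only (no leakage into
validation rows).  Accuracy is reported throughout; the F1 score (positive
class = cases) is added on the imbalanced common test set.

Base learners: an L1-penalized logistic regression (the penalty performs
embedded feature selection; the nonzero support is recorded) and a random
forest.  The registry accepts any object with ``fit(X, y)`` and
``predict_proba(X)`` so further learners (e.g. neural networks trained
elsewhere) can be plugged in.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "CVPlan",
    "NormalizationParams",
    "TrainedModel",
    "EvalMetrics",
    "balance_classes",
    "make_cv_plan",
    "fit_normalizer",
    "apply_normalizer",
    "fit_lr_lasso",
    "fit_rf",
    "CLASSIFIER_REGISTRY",
    "fit_classifier",
    "predict",
    "evaluate",
    "cross_validate",
]

THRESHOLD = 0.5  # decision threshold on soft responses, fixed everywhere


@dataclass
class CVPlan:
    """Fold assignments for repeated stratified k-fold CV on a balanced pool.

    ``folds[r][k]`` is the (train_ids, val_ids) pair of fold ``k`` in repeat
    ``r``.  Each repeat re-balances the pool with its own derived seed
    (base seed + repeat index), then stratifies.
    """

    n_folds: int
    n_repeats: int
    seed: int
    folds: list[list[tuple[list[str], list[str]]]]


@dataclass
class NormalizationParams:
    mean: np.ndarray
    std: np.ndarray
    constant_mask: np.ndarray  # True where the training column was constant


@dataclass
class EvalMetrics:
    accuracy: float
    f1: float


@dataclass
class TrainedModel:
    """A fitted per-source classifier plus its training-set normalization."""

    source: str
    kind: str
    estimator: object
    normalization: NormalizationParams | None
    support: np.ndarray | None = None  # indices with nonzero coefficient (LR)
    train_prevalence: float = 0.5
    converged: bool = True
    feature_names: list[str] = field(default_factory=list)

    def predict_soft(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.normalization is not None:
            X = apply_normalizer(self.normalization, X)
        if self.support is not None and self.support.size == 0:
            # fully shrunk model: intercept-only, respond with training prevalence
            return np.full(X.shape[0], self.train_prevalence)
        return np.asarray(self.estimator.predict_proba(X))[:, 1]

    def predict_hard(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        return (self.predict_soft(X) >= THRESHOLD).astype(int)


def balance_classes(
    ids: Sequence[str],
    labels: Sequence[int] | dict[str, int],
    seed: int,
    method: str = "undersample",
) -> list[str]:
    """Equalize case/control counts by random undersampling of the majority
    class (or oversampling of the minority with ``method='oversample'``).

    Returns ids with exactly ``min(class sizes)`` (or max, for oversampling)
    members per class; deterministic given the seed.
    """
    ids = list(ids)
    if isinstance(labels, dict):
        lab = np.array([labels[i] for i in ids])
    else:
        lab = np.asarray(list(labels))
    pos = [i for i, l in zip(ids, lab) if l == 1]
    neg = [i for i, l in zip(ids, lab) if l == 0]
    if not pos or not neg:
        raise ValueError("both classes must be present to balance")
    rng = np.random.default_rng(seed)
    if method == "undersample":
        m = min(len(pos), len(neg))
        pos = list(rng.choice(pos, size=m, replace=False)) if len(pos) > m else pos
        neg = list(rng.choice(neg, size=m, replace=False)) if len(neg) > m else neg
    elif method == "oversample":
        m = max(len(pos), len(neg))
        if len(pos) < m:
            pos = pos + list(rng.choice(pos, size=m - len(pos), replace=True))
        if len(neg) < m:
            neg = neg + list(rng.choice(neg, size=m - len(neg), replace=True))
    else:
        raise ValueError(f"unknown balancing method {method!r}")
    out = pos + neg
    rng.shuffle(out)
    return out


def make_cv_plan(
    ids: Sequence[str],
    labels: dict[str, int],
    n_folds: int = 10,
    n_repeats: int = 10,
    seed: int = 0,
    rebalance_per_repeat: bool = True,
) -> CVPlan:
    """Repeated stratified k-fold plan on a class-balanced pool.

    Each repeat uses a derived seed (``seed + repeat``); by default the
    balancing resample is redrawn each repeat so the discarded majority
    subjects rotate through the folds.
    """
    ids = list(ids)
    base_balanced = balance_classes(ids, labels, seed)
    n_per_class = sum(labels[i] for i in base_balanced)
    if n_folds > n_per_class:
        raise ValueError(f"n_folds={n_folds} exceeds per-class size {n_per_class}")
    folds: list[list[tuple[list[str], list[str]]]] = []
    for r in range(n_repeats):
        rep_seed = seed + r
        pool = balance_classes(ids, labels, rep_seed) if rebalance_per_repeat else base_balanced
        y = np.array([labels[i] for i in pool])
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rep_seed)
        rep = []
        for tr, va in skf.split(np.zeros(len(pool)), y):
            rep.append(([pool[i] for i in tr], [pool[i] for i in va]))
        folds.append(rep)
    return CVPlan(n_folds=n_folds, n_repeats=n_repeats, seed=seed, folds=folds)


def fit_normalizer(X_train: np.ndarray) -> NormalizationParams:
    """Column means/stds of the training rows.  Constant columns get std
    guarded to 1 (they normalize to all-zeros) and are flagged."""
    X_train = np.asarray(X_train, dtype=float)
    if X_train.size == 0:
        raise ValueError("empty training matrix")
    mean = X_train.mean(axis=0)
    std = X_train.std(axis=0, ddof=0)
    constant = std == 0
    std = np.where(constant, 1.0, std)
    return NormalizationParams(mean=mean, std=std, constant_mask=constant)


def apply_normalizer(params: NormalizationParams, X: np.ndarray) -> np.ndarray:
    return (np.asarray(X, dtype=float) - params.mean) / params.std


def _lambda_grid_logistic(X: np.ndarray, y: np.ndarray, n: int = 10) -> np.ndarray:
    # smallest lambda that zeroes the whole coefficient vector, then 4 decades down
    lam_max = np.abs(X.T @ (y - y.mean())).max()
    lam_max = max(lam_max, 1e-6)
    return np.logspace(np.log10(lam_max), np.log10(lam_max) - 4, n)


def fit_lr_lasso(
    X_train: np.ndarray,
    y_train: np.ndarray,
    lambda_grid: Sequence[float] | None = None,
    cv_seed: int = 0,
    n_inner_folds: int = 5,
    source: str = "",
    feature_names: Sequence[str] | None = None,
) -> TrainedModel:
    """L1-penalized logistic regression with the penalty weight chosen by
    inner stratified CV accuracy over a log-spaced grid.

    The grid runs from the full-shrinkage point (all coefficients zero)
    down four decades.  The fitted model records its nonzero support; a
    fully shrunk model predicts the training prevalence.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    norm = fit_normalizer(X_train)
    Xn = apply_normalizer(norm, X_train)
    if lambda_grid is None:
        lambda_grid = _lambda_grid_logistic(Xn, y_train)
    lambda_grid = np.asarray(sorted(lambda_grid, reverse=True), dtype=float)

    def _fit(lam: float, X: np.ndarray, y: np.ndarray) -> LogisticRegression:
        C = 1.0 / max(lam, 1e-12)
        return LogisticRegression(
            l1_ratio=1.0, C=C, solver="liblinear", max_iter=2000, random_state=0
        ).fit(X, y)

    best_lam, best_acc = float(lambda_grid[0]), -np.inf
    if len(lambda_grid) > 1:
        k = min(n_inner_folds, int(np.bincount(y_train).min()))
        skf = StratifiedKFold(n_splits=max(k, 2), shuffle=True, random_state=cv_seed)
        accs = np.zeros(len(lambda_grid))
        for tr, va in skf.split(Xn, y_train):
            for j, lam in enumerate(lambda_grid):
                m = _fit(lam, Xn[tr], y_train[tr])
                accs[j] += accuracy_score(y_train[va], m.predict(Xn[va]))
        best_lam = float(lambda_grid[int(np.argmax(accs))])
    clf = _fit(best_lam, Xn, y_train)
    support = np.flatnonzero(np.abs(clf.coef_[0]) > 0)
    return TrainedModel(
        source=source,
        kind="lr",
        estimator=clf,
        normalization=norm,
        support=support,
        train_prevalence=float(y_train.mean()),
        converged=bool(clf.n_iter_[0] < clf.max_iter),
        feature_names=list(feature_names or []),
    )


def fit_rf(
    X_train: np.ndarray,
    y_train: np.ndarray,
    seed: int = 0,
    n_estimators: int = 500,
    source: str = "",
    feature_names: Sequence[str] | None = None,
    **hyperparams,
) -> TrainedModel:
    """Random forest wrapper; soft response = fraction of trees voting case.
    Trees do not need normalized inputs but the shared normalization is
    applied anyway for protocol uniformity (monotone per-feature, harmless).
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=int)
    norm = fit_normalizer(X_train)
    rf = RandomForestClassifier(
        n_estimators=n_estimators, max_features="sqrt", random_state=seed, **hyperparams
    ).fit(apply_normalizer(norm, X_train), y_train)
    return TrainedModel(
        source=source,
        kind="rf",
        estimator=rf,
        normalization=norm,
        support=None,
        train_prevalence=float(y_train.mean()),
        feature_names=list(feature_names or []),
    )


CLASSIFIER_REGISTRY: dict[str, Callable[..., TrainedModel]] = {
    "lr": fit_lr_lasso,
    "rf": fit_rf,
}


def fit_classifier(kind: str, X_train, y_train, seed: int = 0, **kwargs) -> TrainedModel:
    """Dispatch through the registry.  ``kind`` may also be a callable with
    the ``fit_*`` signature, enabling external plug-in learners.  Keyword
    arguments not accepted by the chosen fitter are silently dropped so one
    bundle of settings can serve a mixed classifier list."""
    import inspect

    if callable(kind):
        return kind(X_train, y_train, seed=seed, **kwargs)
    if kind == "lr":
        fn, seed_kw = fit_lr_lasso, "cv_seed"
    elif kind == "rf":
        fn, seed_kw = fit_rf, "seed"
    else:
        raise KeyError(f"unknown classifier kind {kind!r}")
    accepted = set(inspect.signature(fn).parameters)
    kw = {k: v for k, v in kwargs.items() if k in accepted}
    kw[seed_kw] = seed
    return fn(X_train, y_train, **kw)


def predict(model: TrainedModel, X) -> tuple[np.ndarray, np.ndarray]:
    """Return (hard, soft) responses; hard = soft >= 0.5."""
    soft = model.predict_soft(X)
    return (soft >= THRESHOLD).astype(int), soft


def evaluate(hard_preds, soft_preds, labels) -> EvalMetrics:
    """Accuracy and F1 (positive class = cases).  F1 is 0 when there are no
    true or predicted positives."""
    hard_preds = np.asarray(hard_preds, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if hard_preds.shape != labels.shape:
        raise ValueError("prediction/label length mismatch")
    return EvalMetrics(
        accuracy=float(accuracy_score(labels, hard_preds)),
        f1=float(f1_score(labels, hard_preds, pos_label=1, zero_division=0)),
    )


def cross_validate(
    kind: str,
    X: pd.DataFrame,
    labels: dict[str, int],
    plan: CVPlan,
    seed: int = 0,
    **fit_kwargs,
) -> pd.DataFrame:
    """Run a classifier through a CV plan; one row per (repeat, fold).

    ``X`` is indexed by subject id.  Normalization is fit inside each fold on
    its training rows only.
    """
    rows = []
    for r, rep in enumerate(plan.folds):
        for k, (tr_ids, va_ids) in enumerate(rep):
            Xtr = X.loc[tr_ids].to_numpy(dtype=float)
            ytr = np.array([labels[i] for i in tr_ids])
            Xva = X.loc[va_ids].to_numpy(dtype=float)
            yva = np.array([labels[i] for i in va_ids])
            model = fit_classifier(kind, Xtr, ytr, seed=seed + r, **fit_kwargs)
            hard, soft = predict(model, Xva)
            m = evaluate(hard, soft, yva)
            rows.append({"repeat": r, "fold": k, "accuracy": m.accuracy, "f1": m.f1})
    return pd.DataFrame(rows)


def serialize_lr(model: TrainedModel) -> str:
    """JSON round-trip for linear models (coefficients, support, normalization)."""
    if model.kind != "lr":
        raise ValueError("only linear models serialize to JSON")
    obj = {
        "source": model.source,
        "kind": model.kind,
        "coef": model.estimator.coef_[0].tolist(),
        "intercept": float(model.estimator.intercept_[0]),
        "support": model.support.tolist(),
        "mean": model.normalization.mean.tolist(),
        "std": model.normalization.std.tolist(),
        "train_prevalence": model.train_prevalence,
        "feature_names": model.feature_names,
    }
    return json.dumps(obj)
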