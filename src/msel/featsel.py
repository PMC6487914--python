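"""Feature selection: LASSO, Sparse-Group LASSO, and the two competing
selection pipelines for source-wise missing cohorts.

Both penalised least-squares problems regress the binary label directly
(the selected support is then handed to a logistic model for classification,
so the squared-error objective is only a selection device):

* LASSO          0.5 ||y - X b||^2 + lam ||b||_1
* SG-LASSO       0.5 ||y - X b||^2 + lam1 ||b||_1
                                   + lam2 * sum_i sqrt(p_i) ||b_i||_2

where the groups ``b_i`` are the per-source coefficient blocks and ``p_i``
the per-source feature counts.  The group term drives whole sources to zero
(source-level sparsity) on top of the feature-level sparsity of the l1 term.

Two pipelines use them:

* Complete Dataset Learning (CDL): select on the complete-data subjects
  only, discarding every subject with a missing source.
* Incomplete Dataset Learning (IDL): stage 1 runs a per-source LASSO on all
  incomplete-data contributors of that source (far more rows than CDL has);
  the union of nonzero features is then taken from the complete-data matrix
  and stage 2 runs SG-LASSO on that restriction.

Solvers are cyclic (block) coordinate descent with soft-threshold /
group-soft-threshold proximal steps; convergence is declared on the relative
objective change and checked against the subgradient optimality conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .classifiers import apply_normalizer, balance_classes, fit_normalizer
from .cohort import MultiSourceCohort, Partition, complete_design_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "WeightVector",
    "ISLSelection",
    "lasso_objective",
    "sg_lasso_objective",
    "solve_lasso",
    "solve_sg_lasso",
    "lambda_max_lasso",
    "complete_dataset_learning",
    "incomplete_dataset_learning",
    "rank_features",
]


@dataclass
class WeightVector:
    """A fitted coefficient vector with its regularization metadata."""

    beta: np.ndarray
    group_index: np.ndarray
    lambdas: dict[str, float]
    intercept: float = 0.0
    feature_names: list[str] = field(default_factory=list)
    converged: bool = True
    kkt_residual: float = 0.0

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.beta != 0)


@dataclass
class ISLSelection:
    """Result of the two-stage incomplete-data selection.

    ``beta_isl``/``stage1_columns`` is the concatenation of the nonzero
    stage-1 per-source weights and their column indices into the complete
    design matrix; ``stage2`` is the SG-LASSO fit on that restriction, and
    ``final_columns`` the columns surviving both stages.
    """

    beta_isl: np.ndarray
    stage1_columns: np.ndarray
    stage2: WeightVector
    final_columns: np.ndarray
    feature_names: list[str] = field(default_factory=list)


def _soft(z: np.ndarray | float, t: float):
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)


def lasso_objective(X, y, beta, lam: float) -> float:
    r = y - X @ beta
    return 0.5 * float(r @ r) + lam * float(np.abs(beta).sum())


def sg_lasso_objective(X, y, beta, lam1: float, lam2: float, groups) -> float:
    r = y - X @ beta
    val = 0.5 * float(r @ r) + lam1 * float(np.abs(beta).sum())
    for g in np.unique(groups):
        bg = beta[groups == g]
        val += lam2 * np.sqrt(bg.size) * float(np.linalg.norm(bg))
    return val


def lambda_max_lasso(X, y) -> float:
    """Smallest penalty at which the LASSO solution is identically zero."""
    return float(np.abs(X.T @ y).max())


def solve_lasso(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    beta0: np.ndarray | None = None,
) -> WeightVector:
    """Cyclic coordinate descent for the l1-penalised least-squares problem.

    Each sweep minimises the objective exactly in one coordinate via
    soft-thresholding, so the objective is non-increasing; convergence is
    declared when its relative change falls below ``tol``.  The result
    carries the maximum violation of the subgradient conditions
    (|X_j' r| <= lam on the zero set, = lam*sign(b_j) elsewhere).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if lam < 0:
        raise ValueError("lam must be >= 0")
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    col_sq = (X**2).sum(axis=0)
    r = y - X @ beta
    obj = lasso_objective(X, y, beta, lam)
    converged = False
    for _ in range(max_iter):
        for j in range(p):
            if col_sq[j] == 0:
                beta[j] = 0.0
                continue
            bj_old = beta[j]
            z = X[:, j] @ r + col_sq[j] * bj_old
            bj_new = _soft(z, lam) / col_sq[j]
            if bj_new != bj_old:
                r += X[:, j] * (bj_old - bj_new)
                beta[j] = bj_new
        new_obj = lasso_objective(X, y, beta, lam)
        if obj - new_obj <= tol * max(1.0, abs(obj)):
            obj = new_obj
            converged = True
            break
        obj = new_obj
    beta[np.abs(beta) < 1e-12] = 0.0  # clear float dust at the threshold boundary
    grad = X.T @ (y - X @ beta)
    viol_zero = np.maximum(np.abs(grad[beta == 0]) - lam, 0.0)
    viol_nz = np.abs(grad[beta != 0] - lam * np.sign(beta[beta != 0]))
    kkt = float(max(viol_zero.max(initial=0.0), viol_nz.max(initial=0.0)))
    if not converged:
        logger.warning("LASSO did not converge in %d sweeps (KKT residual %.3g)", max_iter, kkt)
    return WeightVector(
        beta=beta,
        group_index=np.zeros(p, dtype=int),
        lambdas={"lam": lam},
        converged=converged,
        kkt_residual=kkt,
    )


def _group_prox_step(Xg, r_g, bg, lam1, lam2w, L, n_inner=50, tol=1e-9):
    # proximal gradient on one group's subproblem; r_g excludes this group's fit
    t = 1.0 / L
    for _ in range(n_inner):
        grad = Xg.T @ (Xg @ bg - r_g)
        u = _soft(bg - t * grad, t * lam1)
        nrm = np.linalg.norm(u)
        new = np.zeros_like(bg) if nrm == 0 else max(0.0, 1.0 - t * lam2w / nrm) * u
        if np.abs(new - bg).max() <= tol * max(1.0, np.abs(bg).max()):
            bg = new
            break
        bg = new
    return bg


def solve_sg_lasso(
    X: np.ndarray,
    y: np.ndarray,
    lam1: float,
    lam2: float,
    groups: Sequence[int],
    tol: float = 1e-8,
    max_iter: int = 10_000,
    beta0: np.ndarray | None = None,
) -> WeightVector:
    """Block coordinate descent for the sparse-group penalty.

    Per sweep each group is either set exactly to zero — when the
    group-level condition ||soft(X_g' r, lam1)||_2 <= lam2*sqrt(p_g) holds —
    or updated by proximal-gradient steps on its subproblem.  With lam2 = 0
    the problem is the plain LASSO and the solutions coincide.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups, dtype=int)
    if lam1 < 0 or lam2 < 0:
        raise ValueError("penalties must be >= 0")
    if groups.shape[0] != X.shape[1]:
        raise ValueError("groups must label every column")
    p = X.shape[1]
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    gids = np.unique(groups)
    gmask = {g: groups == g for g in gids}
    L = {}
    for g in gids:
        Xg = X[:, gmask[g]]
        # largest eigenvalue of Xg'Xg = squared spectral norm
        L[g] = max(float(np.linalg.norm(Xg, 2) ** 2), 1e-12)
    obj = sg_lasso_objective(X, y, beta, lam1, lam2, groups)
    resid = y - X @ beta
    converged = False
    for _ in range(max_iter):
        for g in gids:
            m = gmask[g]
            Xg = X[:, m]
            bg = beta[m]
            r_g = resid + Xg @ bg  # residual with this group removed
            w = lam2 * np.sqrt(m.sum())
            if np.linalg.norm(_soft(Xg.T @ r_g, lam1)) <= w:
                new = np.zeros_like(bg)
            else:
                new = _group_prox_step(Xg, r_g, bg.copy(), lam1, w, L[g])
            beta[m] = new
            resid = r_g - Xg @ new
        new_obj = sg_lasso_objective(X, y, beta, lam1, lam2, groups)
        if obj - new_obj <= tol * max(1.0, abs(obj)):
            obj = new_obj
            converged = True
            break
        obj = new_obj
    beta[np.abs(beta) < 1e-12] = 0.0
    # KKT: zero groups must satisfy the group-threshold condition
    kkt = 0.0
    r = y - X @ beta
    for g in gids:
        m = gmask[g]
        if not beta[m].any():
            w = lam2 * np.sqrt(m.sum())
            kkt = max(kkt, float(np.linalg.norm(_soft(X[:, m].T @ r, lam1)) - w))
    kkt = max(kkt, 0.0)
    if not converged:
        logger.warning("SG-LASSO did not converge in %d sweeps", max_iter)
    return WeightVector(
        beta=beta,
        group_index=groups,
        lambdas={"lam1": lam1, "lam2": lam2},
        converged=converged,
        kkt_residual=kkt,
    )


# ---------------------------------------------------------------------------
# Downstream logistic evaluation of a selected support.


def _lr_cv_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    support: np.ndarray,
    seed: int,
    n_folds: int = 5,
    n_repeats: int = 3,
    balance: bool = True,
) -> float:
    """Leakage-safe repeated-CV accuracy of an unpenalised logistic model
    restricted to ``support``.  Each repeat redraws the class-balancing
    resample (derived seed), which keeps the estimate stable enough to
    compare penalty-grid points on small complete-data sets.  Intercept-only
    (empty support) scores by majority class."""
    y = np.asarray(y, dtype=int)
    all_ids = np.arange(len(y))
    labels = {i: int(y[i]) for i in all_ids}
    accs = []
    for r in range(n_repeats):
        ids = all_ids
        if balance:
            ids = np.asarray(sorted(balance_classes(list(all_ids), labels, seed + r)))
        Xs, ys = X[ids], y[ids]
        k = min(n_folds, int(np.bincount(ys).min()))
        if k < 2:
            return float("nan")
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + r)
        for tr, va in skf.split(Xs, ys):
            if support.size == 0:
                maj = int(round(ys[tr].mean()))
                accs.append(float((ys[va] == maj).mean()))
                continue
            norm = fit_normalizer(Xs[np.ix_(tr, support)])
            clf = LogisticRegression(C=np.inf, max_iter=2000).fit(
                apply_normalizer(norm, Xs[np.ix_(tr, support)]), ys[tr]
            )
            accs.append(float(clf.score(apply_normalizer(norm, Xs[np.ix_(va, support)]), ys[va])))
    return float(np.mean(accs))


def _lambda_grid(X, y, n: int = 8, decades: float = 2.0) -> np.ndarray:
    lmax = max(lambda_max_lasso(X, y - y.mean()), 1e-8)
    return np.logspace(np.log10(lmax), np.log10(lmax) - decades, n)


def _standardize(X: np.ndarray) -> np.ndarray:
    norm = fit_normalizer(X)
    return apply_normalizer(norm, X)


def _cv_lasso_lambda(
    X: np.ndarray, y: np.ndarray, grid: np.ndarray, seed: int, n_folds: int = 5
) -> float:
    """Pick the LASSO penalty minimising k-fold squared prediction error
    (the standard pathwise CV rule), warm-starting along the path."""
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    fold = rng.integers(0, n_folds, size=n)
    errs = np.zeros(len(grid))
    for f in range(n_folds):
        tr, va = fold != f, fold == f
        if va.sum() == 0 or tr.sum() == 0:
            continue
        warm = None
        for j, lam in enumerate(sorted(grid, reverse=True)):
            wv = solve_lasso(X[tr], y[tr], lam * tr.sum() / n, beta0=warm)
            warm = wv.beta
            r = y[va] - X[va] @ wv.beta
            errs[j] += float(r @ r)
    return float(sorted(grid, reverse=True)[int(np.argmin(errs))])


def complete_dataset_learning(
    cohort: MultiSourceCohort,
    partition: Partition,
    estimator: str = "sg_lasso",
    n_lambda: int = 8,
    seed: int = 0,
    cv_folds: int = 5,
) -> tuple[WeightVector, dict]:
    """Select features using only the complete-data subjects.

    Builds the concatenated complete design matrix, standardizes it, and
    fits LASSO (``estimator='lasso'``) or SG-LASSO over a log-spaced penalty
    grid; the grid point is chosen by the cross-validated accuracy of a
    downstream logistic model on the selected support (ties favour the
    sparser fit).  Returns the winning weight vector and CV metrics.
    """
    Xdf, y, groups = complete_design_matrix(cohort, partition)
    if len(Xdf) < cv_folds:
        raise ValueError(f"too few complete subjects ({len(Xdf)}) for {cv_folds}-fold CV")
    Xraw = Xdf.to_numpy(dtype=float)
    X = _standardize(Xraw)
    yv = y.to_numpy(dtype=float)
    yc = yv - yv.mean()
    grid1 = _lambda_grid(X, yv, n=n_lambda)
    cands: list[WeightVector] = []
    if estimator == "lasso":
        warm = None
        for lam in grid1:  # descending path, warm-started
            wv = solve_lasso(X, yc, lam, beta0=warm)
            warm = wv.beta
            cands.append(wv)
    elif estimator == "sg_lasso":
        grid2 = np.concatenate([[0.0], _lambda_grid(X, yv, n=n_lambda - 1)])
        for lam2 in grid2:
            warm = None
            for lam1 in grid1:
                wv = solve_sg_lasso(X, yc, lam1, lam2, groups, beta0=warm)
                warm = wv.beta
                cands.append(wv)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    best, best_key = None, (-np.inf, np.inf)
    acc_cache: dict[tuple, float] = {}
    for wv in cands:
        sup_key = tuple(wv.support.tolist())
        if sup_key not in acc_cache:
            acc_cache[sup_key] = _lr_cv_accuracy(Xraw, yv.astype(int), wv.support, seed, cv_folds)
        key = (acc_cache[sup_key], -wv.support.size)
        if key > best_key:
            best, best_key = wv, key
    best.group_index = groups
    best.feature_names = list(Xdf.columns)
    best.intercept = float(yv.mean())
    metrics = {
        "cv_accuracy": float(best_key[0]),
        "support_size": int(best.support.size),
        "n_complete": int(len(Xdf)),
        "p": int(X.shape[1]),
    }
    return best, metrics


def incomplete_dataset_learning(
    cohort: MultiSourceCohort,
    partition: Partition,
    n_lambda: int = 8,
    seed: int = 0,
    cv_folds: int = 5,
) -> tuple[ISLSelection, dict]:
    """Two-stage selection exploiting the incomplete-data subjects.

    Stage 1: within each source, LASSO on *all* incomplete-data contributors
    of that source (test subjects excluded), penalty chosen by downstream
    logistic CV accuracy.  The nonzero weights are concatenated across
    sources.  Stage 2: the surviving columns are taken from the complete
    design matrix and SG-LASSO is run on that restriction; the final support
    is evaluated by logistic CV on the complete-data subjects.
    """
    spec = cohort.spec
    idx = {s.id: s for s in cohort.subjects}
    col_names: list[str] = []
    col_src: list[str] = []
    for src in spec.names:
        for f in spec.feature_names[src]:
            col_names.append(f"{src}::{f}")
            col_src.append(src)
    offsets = {}
    off = 0
    for src in spec.names:
        offsets[src] = off
        off += len(spec.feature_names[src])

    beta_isl_parts: list[np.ndarray] = []
    col_parts: list[np.ndarray] = []
    stage1_shapes = {}
    for src in spec.names:
        ids = partition.train_by_source.get(src, [])
        if not ids:
            raise ValueError(f"source {src!r} has an empty incomplete-data training pool")
        Xs = np.asarray([idx[i].source_data[src] for i in ids], dtype=float)
        ys = np.asarray([idx[i].label for i in ids], dtype=float)
        stage1_shapes[src] = Xs.shape
        Xn = _standardize(Xs)
        yc = ys - ys.mean()
        lam = _cv_lasso_lambda(Xn, yc, _lambda_grid(Xn, ys, n=n_lambda), seed, cv_folds)
        best_wv = solve_lasso(Xn, yc, lam)
        sup = best_wv.support
        if sup.size == 0:
            logger.info("stage 1: source %r selected no features", src)
            continue
        beta_isl_parts.append(best_wv.beta[sup])
        col_parts.append(sup + offsets[src])
    if col_parts:
        beta_isl = np.concatenate(beta_isl_parts)
        stage1_cols = np.concatenate(col_parts)
    else:
        beta_isl = np.zeros(0)
        stage1_cols = np.zeros(0, dtype=int)

    Xdf, y, groups = complete_design_matrix(cohort, partition)
    yv = y.to_numpy(dtype=int)
    if stage1_cols.size == 0:
        empty = WeightVector(
            beta=np.zeros(0), group_index=np.zeros(0, dtype=int), lambdas={"lam1": np.inf, "lam2": 0.0}
        )
        sel = ISLSelection(beta_isl, stage1_cols, empty, stage1_cols, [])
        acc = _lr_cv_accuracy(Xdf.to_numpy(dtype=float), yv, np.zeros(0, dtype=int), seed, cv_folds)
        return sel, {"cv_accuracy": acc, "support_size": 0, "stage1_shapes": stage1_shapes}

    X_isl = Xdf.to_numpy(dtype=float)[:, stage1_cols]
    g_isl = groups[stage1_cols]
    Xn = _standardize(X_isl)
    yc = yv - yv.mean()
    grid1 = _lambda_grid(Xn, yv.astype(float), n=n_lambda)
    grid2 = np.concatenate([[0.0], _lambda_grid(Xn, yv.astype(float), n=n_lambda - 1)])
    best_wv, best_key = None, (-np.inf, np.inf)
    acc_cache: dict[tuple, float] = {}
    for lam2 in grid2:
        warm = None
        for lam1 in grid1:
            wv = solve_sg_lasso(Xn, yc, lam1, lam2, g_isl, beta0=warm)
            warm = wv.beta
            sup_key = tuple(wv.support.tolist())
            if sup_key not in acc_cache:
                acc_cache[sup_key] = _lr_cv_accuracy(X_isl, yv, wv.support, seed, cv_folds)
            key = (acc_cache[sup_key], -wv.support.size)
            if key > best_key:
                best_wv, best_key = wv, key
    final_cols = stage1_cols[best_wv.support]
    best_wv.feature_names = [col_names[c] for c in stage1_cols]
    sel = ISLSelection(
        beta_isl=beta_isl,
        stage1_columns=stage1_cols,
        stage2=best_wv,
        final_columns=final_cols,
        feature_names=[col_names[c] for c in final_cols],
    )
    metrics = {
        "cv_accuracy": float(best_key[0]),
        "support_size": int(final_cols.size),
        "stage1_size": int(stage1_cols.size),
        "stage1_shapes": stage1_shapes,
    }
    return sel, metrics


def rank_features(
    w: WeightVector | ISLSelection, k: int = 10, feature_names: Sequence[str] | None = None
) -> pd.DataFrame:
    """Top-k features by |coefficient|, ties broken by (group, column) order.

    If fewer than ``k`` coefficients are nonzero, all nonzero ones are
    returned (logged).  Columns: rank, feature, source_group, beta.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(w, ISLSelection):
        beta = w.stage2.beta[w.stage2.support]
        names = [w.stage2.feature_names[i] for i in w.stage2.support] if w.stage2.feature_names else [
            str(c) for c in w.final_columns
        ]
        groups = w.stage2.group_index[w.stage2.support]
        order_idx = w.stage2.support
    else:
        beta = w.beta[w.support]
        names = (
            [w.feature_names[i] for i in w.support]
            if w.feature_names
            else [str(i) for i in w.support]
        )
        groups = w.group_index[w.support]
        order_idx = w.support
    if feature_names is not None:
        names = [feature_names[i] for i in order_idx]
    nz = len(beta)
    if k > nz:
        logger.info("requested top %d but only %d nonzero coefficients", k, nz)
        k = nz
    order = sorted(range(nz), key=lambda i: (-abs(beta[i]), groups[i], order_idx[i]))[:k]
    return pd.DataFrame(
        {
            "rank": np.arange(1, k + 1),
            "feature": [names[i] for i in order],
            "source_group": [int(groups[i]) for i in order],
            "beta": [float(beta[i]) for i in order],
        }
    )
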