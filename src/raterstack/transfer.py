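"""Cross-site transfer analysis with elastic-net logistic regression.

A child-level model (ASD vs non-ASD) is fit per site on consensus answer
vectors, with the penalty alpha * (rho * ||b||_1 + (1 - rho)/2 * ||b||_2^2)
added to the mean weighted logistic log-loss (intercept unpenalized).
Hyperparameters are grid-searched by cross-validated AUC; the selected model
is evaluated on a same-site held-out split and on the full other site, and
per-feature selection frequencies across CV folds expose which behaviors
each site's model relies on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .data import AnnotationTable

__all__ = [
    "ElasticNetLogistic",
    "GridSearchResult",
    "elastic_net_objective",
    "fit_elastic_net",
    "grid_search_cv",
    "transfer_evaluate",
    "selection_frequency",
    "consensus_features",
    "balanced_sample_weights",
]

DEFAULT_ALPHA_GRID = (1.0, 0.1, 0.01, 0.001)
DEFAULT_RHO_GRID = (0.1, 0.3, 0.5, 0.7, 0.9)
SELECTION_TOL = 1e-8


def balanced_sample_weights(y: np.ndarray) -> np.ndarray:
    """Per-sample weights n / (n_classes * n_c): class weight sums are equal."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    wmap = {c: y.size / (len(classes) * n) for c, n in zip(classes, counts)}
    return np.array([wmap[v] for v in y])


def elastic_net_objective(
    beta: np.ndarray,
    intercept: float,
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    rho: float,
    sample_weight: np.ndarray | None = None,
) -> float:
    """Mean weighted logistic log-loss plus the elastic-net penalty.

    loss = sum_i s_i * log(1 + exp(-t_i * (X_i b + b0))) / sum_i s_i
           + alpha * (rho * sum|b_k| + (1 - rho)/2 * sum b_k^2)
    with t_i = +/-1 and the intercept unpenalized.
    """
    beta = np.asarray(beta, dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    if not (np.isfinite(beta).all() and np.isfinite(X).all() and np.isfinite(intercept)):
        raise ValueError("non-finite inputs")
    s = np.ones(y.size) if sample_weight is None else np.asarray(sample_weight, float)
    t = np.where(y == 1, 1.0, -1.0)
    margin = t * (X @ beta + intercept)
    # stable log(1 + exp(-m))
    losses = np.logaddexp(0.0, -margin)
    data_term = float(np.sum(s * losses) / np.sum(s))
    penalty = alpha * (rho * np.abs(beta).sum() + (1.0 - rho) * 0.5 * np.sum(beta**2))
    return data_term + penalty


def _optimal_intercept(X, y, classes, coef, sample_weight, start=0.0, tol=1e-12):
    """Newton solve for the weighted-logistic intercept at fixed coefficients."""
    pos = classes[1]
    t = (np.asarray(y) == pos).astype(float)
    eta = X @ coef
    b0 = start
    for _ in range(100):
        p = 1.0 / (1.0 + np.exp(-(eta + b0)))
        grad = float(np.sum(sample_weight * (p - t)))
        hess = float(np.sum(sample_weight * p * (1.0 - p)))
        if hess <= 0:
            break
        step = grad / hess
        b0 -= step
        if abs(step) < tol:
            break
    return b0


class ElasticNetLogistic(BaseEstimator, ClassifierMixin):
    """Elastic-net penalized logistic regression in the objective above.

    Parameters
    ----------
    alpha : overall regularization strength (0 disables the penalty).
    rho : L1/L2 mixing, 1 = pure lasso, 0 = pure ridge.
    class_weight : "balanced" (default, weights n/(2 n_c)) or None.
    max_iter, tol : optimizer budget and stopping tolerance.
    random_state : seed for the saga solver's sampling.
    """

    def __init__(
        self,
        alpha: float = 0.1,
        rho: float = 0.5,
        class_weight: str | None = "balanced",
        max_iter: int = 10000,
        tol: float = 1e-7,
        random_state: int = 0,
    ) -> None:
        self.alpha = alpha
        self.rho = rho
        self.class_weight = class_weight
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _sample_weight(self, y: np.ndarray) -> np.ndarray:
        if self.class_weight == "balanced":
            return balanced_sample_weights(y)
        if self.class_weight is None:
            return np.ones(len(y))
        raise ValueError(f"unsupported class_weight {self.class_weight!r}")

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(f"need exactly 2 classes, got {list(classes)}")
        if self.alpha < 0 or not 0.0 <= self.rho <= 1.0:
            raise ValueError("alpha must be >= 0 and rho in [0, 1]")
        sw = self._sample_weight(y)
        if self.alpha == 0.0:
            inner = LogisticRegression(
                C=np.inf, solver="lbfgs", max_iter=self.max_iter, tol=self.tol
            )
        else:
            # sklearn's saga objective is sum_i s_i * logloss_i + (1/C) * pen;
            # ours is the per-unit-weight mean plus alpha * pen, so C = 1/(W*alpha)
            W = float(sw.sum())
            inner = LogisticRegression(
                solver="saga",
                l1_ratio=self.rho,
                C=1.0 / (W * self.alpha),
                max_iter=self.max_iter,
                tol=self.tol,
                random_state=self.random_state,
            )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            inner.fit(X, y, sample_weight=sw)
        self.converged_ = not any(
            w.category.__name__ == "ConvergenceWarning" for w in caught
        )
        if not self.converged_:
            warnings.warn(
                f"elastic-net fit did not converge in {self.max_iter} iterations",
                stacklevel=2,
            )
        # the intercept is unpenalized, so given beta its optimum is a 1-D
        # convex problem; polish it exactly (saga's step size is tied to the
        # penalty strength and leaves the intercept short at large alpha)
        b0 = _optimal_intercept(X, y, inner.classes_, inner.coef_.ravel(), sw,
                                start=float(inner.intercept_[0]))
        inner.intercept_ = np.array([b0])
        self.inner_ = inner
        self.classes_ = inner.classes_
        self.coef_ = inner.coef_.ravel()
        self.intercept_ = float(inner.intercept_[0])
        self.n_iter_ = int(np.atleast_1d(inner.n_iter_)[0])
        self.sample_weight_ = sw
        return self

    def predict_proba(self, X):
        return self.inner_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X):
        return self.inner_.predict(np.asarray(X, dtype=float))

    def decision_function(self, X):
        return self.inner_.decision_function(np.asarray(X, dtype=float))

    def objective(self, X, y) -> float:
        """This model's training objective evaluated at the fitted coefficients."""
        return elastic_net_objective(
            self.coef_, self.intercept_, X, y, self.alpha, self.rho, self._sample_weight(y)
        )


def fit_elastic_net(
    X, y, alpha: float, rho: float, class_weight: str | None = "balanced", seed: int = 0
) -> ElasticNetLogistic:
    """Functional wrapper over :class:`ElasticNetLogistic`."""
    return ElasticNetLogistic(
        alpha=alpha, rho=rho, class_weight=class_weight, random_state=seed
    ).fit(X, y)


@dataclass
class GridSearchResult:
    """Per-cell CV scores over the (alpha, rho) grid and the selected pair."""

    table: pd.DataFrame  # columns: alpha, rho, auc, accuracy
    alpha: float
    rho: float
    fold_models: Mapping[tuple[float, float], list[ElasticNetLogistic]] = field(
        default_factory=dict
    )


def grid_search_cv(
    X,
    y,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    rho_grid: Sequence[float] = DEFAULT_RHO_GRID,
    n_folds: int = 3,
    seed: int = 0,
) -> GridSearchResult:
    """Grid search (alpha, rho) by mean cross-validated AUC.

    Ties on mean AUC are broken toward larger alpha (stronger
    regularization), then larger rho (sparser model). Folds whose validation
    split is single-class are skipped with a warning.
    """
    if not len(alpha_grid) or not len(rho_grid):
        raise ValueError("grids must be non-empty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))

    rows = []
    fold_models: dict[tuple[float, float], list[ElasticNetLogistic]] = {}
    for alpha in alpha_grid:
        for rho in rho_grid:
            aucs, accs, models = [], [], []
            for tr, va in splits:
                if len(np.unique(y[va])) < 2:
                    warnings.warn("single-class validation fold skipped", stacklevel=2)
                    continue
                m = fit_elastic_net(X[tr], y[tr], alpha, rho, seed=seed)
                scores = m.decision_function(X[va])
                aucs.append(roc_auc_score(y[va], scores))
                accs.append(accuracy_score(y[va], m.predict(X[va])))
                models.append(m)
            rows.append(
                {
                    "alpha": alpha,
                    "rho": rho,
                    "auc": float(np.mean(aucs)) if aucs else np.nan,
                    "accuracy": float(np.mean(accs)) if accs else np.nan,
                }
            )
            fold_models[(alpha, rho)] = models

    table = pd.DataFrame(rows)
    ranked = table.sort_values(
        ["auc", "alpha", "rho"], ascending=[False, False, False], kind="stable"
    )
    best = ranked.iloc[0]
    return GridSearchResult(
        table=table, alpha=float(best["alpha"]), rho=float(best["rho"]), fold_models=fold_models
    )


def selection_frequency(
    models: Sequence[ElasticNetLogistic],
    feature_names: Sequence[str] | None = None,
    tol: float = SELECTION_TOL,
) -> pd.Series:
    """Count, per feature, the folds in which |beta_k| exceeds numerical zero."""
    if not models:
        raise ValueError("need at least one fitted model")
    counts = np.zeros(models[0].coef_.size, dtype=int)
    for m in models:
        counts += (np.abs(m.coef_) > tol).astype(int)
    names = (
        list(feature_names)
        if feature_names is not None
        else [f"f{i}" for i in range(counts.size)]
    )
    return pd.Series(counts, index=names, name="selection_count")


def consensus_features(table: AnnotationTable) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """One answer vector per child: plurality over raters, ties to lowest code.

    Missing sentinels are ignored unless every rater marked the question
    unratable, in which case the sentinel is kept. Returns (X, y_asd,
    child_ids) with y = 1 for ASD and 0 otherwise.
    """
    qids = table.vocabulary.question_ids
    sentinels = np.array([q.missing_code for q in table.vocabulary.questions])
    child_ids = table.child_ids
    X = np.zeros((len(child_ids), len(qids)), dtype=np.int64)
    for i, cid in enumerate(child_ids):
        rows = table.df[table.df["child_id"] == cid][qids].to_numpy()
        for j in range(len(qids)):
            col = rows[:, j]
            col = col[col != sentinels[j]]
            if col.size == 0:
                X[i, j] = sentinels[j]
            else:
                counts = np.bincount(col)
                X[i, j] = int(np.argmax(counts))  # argmax takes lowest code on ties
    y = np.array([1 if table.children[c].diagnosis == "ASD" else 0 for c in child_ids])
    return X, y, child_ids


def transfer_evaluate(
    train_site: AnnotationTable,
    test_site: AnnotationTable,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    rho_grid: Sequence[float] = DEFAULT_RHO_GRID,
    test_fraction: float = 0.2,
    n_folds: int = 3,
    seed: int = 0,
) -> dict:
    """Train on one site, evaluate same-site held-out and full other site.

    The train site's children are split 80/20 (stratified on the ASD label);
    (alpha, rho) is grid-searched by CV on the 80% portion; the selected
    model is refit on it and scored on the 20% held-out set and on the full
    other site. Also reports per-feature selection frequencies at the
    selected cell.
    """
    X_tr_all, y_tr_all, _ = consensus_features(train_site)
    X_te, y_te, _ = consensus_features(test_site)
    if X_tr_all.shape[1] != X_te.shape[1]:
        raise ValueError("sites disagree on the feature space")

    idx_tr, idx_ho = train_test_split(
        np.arange(len(y_tr_all)),
        test_size=test_fraction,
        stratify=y_tr_all,
        random_state=seed,
    )
    X_tr, y_tr = X_tr_all[idx_tr], y_tr_all[idx_tr]
    X_ho, y_ho = X_tr_all[idx_ho], y_tr_all[idx_ho]

    grid = grid_search_cv(X_tr, y_tr, alpha_grid, rho_grid, n_folds=n_folds, seed=seed)
    model = fit_elastic_net(X_tr, y_tr, grid.alpha, grid.rho, seed=seed)

    def _scores(X, y):
        return {
            "auc": float(roc_auc_score(y, model.decision_function(X))),
            "accuracy": float(accuracy_score(y, model.predict(X))),
        }

    freq = selection_frequency(
        grid.fold_models[(grid.alpha, grid.rho)],
        feature_names=train_site.vocabulary.question_ids,
    )
    return {
        "alpha": grid.alpha,
        "rho": grid.rho,
        "grid": grid,
        "model": model,
        "held_out": _scores(X_ho, y_ho),
        "cross_site": _scores(X_te, y_te),
        "selection_frequency": freq,
    }
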