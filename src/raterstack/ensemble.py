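"""Rater-adaptive ensemble: per-rater random forests, accuracy deltas
against a majority-vote baseline, softmax weights, and the convex-combination
ensemble prediction.

Each rater j gets their own classifier F_j* trained on that rater's
annotations. z_j is the accuracy of F_j* minus the accuracy of the majority
vote of all rater models, both measured on a rater-specific held-out
validation split. Weights are w_j = exp(z_j) / sum_k exp(z_k), so the
ensemble prediction is the convex combination sum_j w_j * p_j of the rater
models' predicted class probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import ParameterSampler, train_test_split

from .data import AnnotationTable, encode_matrix

__all__ = [
    "RaterModel",
    "WeightVector",
    "softmax_weights",
    "majority_vote",
    "accuracy_delta",
    "train_rater_model",
    "ensemble_predict",
    "RaterEnsembleClassifier",
]


@dataclass
class RaterModel:
    """A fitted per-rater classifier plus its held-out validation accuracy."""

    rater_id: str
    estimator: RandomForestClassifier
    classes: np.ndarray
    validation_accuracy: float
    config: dict = field(default_factory=dict)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict_proba(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(X)


@dataclass(frozen=True)
class WeightVector:
    """Softmax weights over raters, aligned with their accuracy deltas."""

    rater_ids: tuple[str, ...]
    z: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        if len(self.rater_ids) != len(self.z) or len(self.z) != len(self.w):
            raise ValueError("rater_ids, z and w must have equal length")
        if abs(float(self.w.sum()) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        # softmax output is strictly positive; hand-built vectors may carry
        # exact zeros (degenerate weights), but never negative mass
        if (self.w < 0).any():
            raise ValueError("weights must be non-negative")

    def as_series(self) -> pd.Series:
        return pd.Series(self.w, index=list(self.rater_ids), name="weight")


def softmax_weights(
    z: Sequence[float] | np.ndarray,
    rater_ids: Sequence[str] | None = None,
    temperature: float = 1.0,
) -> WeightVector:
    """w_j = exp(z_j / T) / sum_k exp(z_k / T), computed with max-subtraction."""
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValueError("z must be non-empty")
    if not np.isfinite(z).all():
        raise ValueError("z must be finite")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    s = z / temperature
    e = np.exp(s - s.max())
    w = e / e.sum()
    ids = tuple(rater_ids) if rater_ids is not None else tuple(f"rater_{i}" for i in range(z.size))
    return WeightVector(rater_ids=ids, z=z, w=w)


def majority_vote(
    votes: Mapping[str, Sequence] | pd.DataFrame,
    prevalence: Mapping[str, int] | None = None,
    class_order: Sequence[str] | None = None,
) -> pd.Series:
    """Plurality label per child over the rater models' predicted labels.

    ``votes``: child_id -> sequence of predicted labels (NaNs/None skipped).
    Ties are broken by global class prevalence in the training labels
    (higher first), then by fixed class order.
    """
    if isinstance(votes, pd.DataFrame):
        votes = {c: row.dropna().tolist() for c, row in votes.iterrows()}
    prevalence = dict(prevalence or {})
    out = {}
    for child, labels in votes.items():
        labels = [l for l in labels if l is not None and l == l]  # drop None/NaN
        if not labels:
            raise ValueError(f"child {child!r} has no votes")
        counts: dict = {}
        for l in labels:
            counts[l] = counts.get(l, 0) + 1
        order = class_order if class_order is not None else sorted(counts)
        best = max(
            counts,
            key=lambda l: (counts[l], prevalence.get(l, 0), -list(order).index(l)),
        )
        out[child] = best
    return pd.Series(out, name="consensus")


def accuracy_delta(
    y_true: Sequence, y_model: Sequence, y_baseline: Sequence
) -> float:
    """z_j = acc(model) - acc(majority-vote baseline) on the same validation set."""
    y_true = np.asarray(y_true)
    if y_true.size == 0:
        raise ValueError("validation set is empty")
    acc_m = float(np.mean(np.asarray(y_model) == y_true))
    acc_b = float(np.mean(np.asarray(y_baseline) == y_true))
    return acc_m - acc_b


_DEFAULT_RF = dict(n_estimators=500, max_depth=None)

_TUNE_SPACE = {
    "max_depth": [None, 4, 8, 16],
    "min_samples_leaf": [1, 2, 4],
    "max_features": ["sqrt", 0.5, None],
}


def train_rater_model(
    table: AnnotationTable,
    rater_id: str,
    labels: Mapping[str, object],
    config: dict | None = None,
    seed: int = 0,
) -> RaterModel:
    """Fit one rater's random forest on that rater's annotations.

    ``labels`` maps child_id to the class label for the layer being trained.
    Raises on single-class training data.
    """
    X, _, child_ids = encode_matrix(table, rater_id)
    y = np.array([labels[c] for c in child_ids])
    return _fit_rater_forest(rater_id, X, y, config or {}, seed)


def _fit_rater_forest(rater_id, X, y, config, seed, validation_accuracy=np.nan):
    if len(np.unique(y)) < 2:
        raise ValueError(f"rater {rater_id!r}: training labels contain a single class")
    params = dict(_DEFAULT_RF)
    params.update({k: v for k, v in config.items() if k in RandomForestClassifier().get_params()})
    est = RandomForestClassifier(random_state=seed, **params)
    est.fit(X, y)
    return RaterModel(
        rater_id=rater_id,
        estimator=est,
        classes=est.classes_,
        validation_accuracy=float(validation_accuracy),
        config={**params, "seed": seed},
    )


def ensemble_predict(
    models: Sequence[RaterModel],
    weights: WeightVector,
    table: AnnotationTable,
    target_class,
) -> pd.DataFrame:
    """Weighted convex combination of per-rater target-class probabilities.

    Returns a DataFrame indexed by child_id with the ensemble probability,
    each covering rater's probability (NaN if not covering) and the weight
    actually used (renormalized over covering raters).
    """
    by_rater = {m.rater_id: m for m in models}
    wmap = dict(zip(weights.rater_ids, weights.w))
    missing = set(wmap) - set(by_rater)
    if missing:
        raise ValueError(f"weights refer to raters without models: {sorted(missing)}")

    # per-rater probabilities for the children each rater covers
    probs: dict[str, pd.Series] = {}
    for rid in weights.rater_ids:
        if rid not in table.rater_ids:
            continue
        X, _, child_ids = encode_matrix(table, rid)
        m = by_rater[rid]
        ti = int(np.flatnonzero(m.classes == target_class)[0]) if target_class in m.classes else None
        if ti is None:
            raise ValueError(f"target class {target_class!r} unknown to rater {rid!r} model")
        probs[rid] = pd.Series(m.predict_proba(X)[:, ti], index=child_ids)

    children = table.child_ids
    p = pd.DataFrame(index=children, columns=list(weights.rater_ids), dtype=float)
    for rid, s in probs.items():
        p.loc[s.index, rid] = s

    w_raw = pd.Series(wmap)
    covered = p.notna()
    if (~covered.any(axis=1)).any():
        orphan = covered.index[~covered.any(axis=1)][0]
        raise ValueError(f"child {orphan!r} has no annotations from any weighted rater")
    w_used = covered.mul(w_raw, axis=1)
    w_used = w_used.div(w_used.sum(axis=1), axis=0)
    ensemble = (p.fillna(0.0) * w_used).sum(axis=1)

    out = pd.DataFrame({"ensemble": ensemble})
    for rid in weights.rater_ids:
        out[f"p_{rid}"] = p[rid]
        out[f"w_{rid}"] = w_used[rid]
    return out


class RaterEnsembleClassifier:
    """Rater-adaptive weighted ensemble of per-rater random forests.

    Follows the scikit-learn estimator idiom (``fit`` / ``predict_proba`` /
    ``get_params`` with trailing-underscore fitted attributes), but ``fit``
    takes an :class:`AnnotationTable` of grouped (child, rater) rows rather
    than a flat feature matrix, so it is not pipeline-composable.

    Parameters
    ----------
    n_estimators, max_depth : forest size per rater model.
    temperature : softmax temperature on the accuracy deltas (1 = as printed).
    baseline : "plurality" scores each rater against the majority vote of the
        rater models; "majority_class" against a constant most-frequent-label
        predictor.
    val_fraction : fraction of each rater's children held out (stratified) to
        measure the accuracy delta z_j.
    refit_full : refit each rater model on all of that rater's children after
        the delta is measured.
    tune : optional small randomized hyperparameter search per rater model,
        scored on the held-out split.
    """

    def __init__(
        self,
        n_estimators: int = 500,
        max_depth: int | None = None,
        temperature: float = 1.0,
        baseline: str = "plurality",
        val_fraction: float = 0.25,
        refit_full: bool = True,
        tune: bool = False,
        n_tune_iter: int = 10,
        random_state: int = 0,
    ) -> None:
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.temperature = temperature
        self.baseline = baseline
        self.val_fraction = val_fraction
        self.refit_full = refit_full
        self.tune = tune
        self.n_tune_iter = n_tune_iter
        self.random_state = random_state

    # minimal get/set_params so sklearn's clone() works
    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "n_estimators",
                "max_depth",
                "temperature",
                "baseline",
                "val_fraction",
                "refit_full",
                "tune",
                "n_tune_iter",
                "random_state",
            )
        }

    def set_params(self, **params) -> "RaterEnsembleClassifier":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- fitting -----------------------------------------------------------

    def _rf_config(self) -> dict:
        return {"n_estimators": self.n_estimators, "max_depth": self.max_depth}

    def _split(self, child_ids, y):
        """Stratified rater-specific validation split, deterministic in seed."""
        try:
            tr, va = train_test_split(
                np.arange(len(child_ids)),
                test_size=self.val_fraction,
                stratify=y,
                random_state=self.random_state,
            )
        except ValueError:  # a class too small to stratify
            tr, va = train_test_split(
                np.arange(len(child_ids)),
                test_size=self.val_fraction,
                random_state=self.random_state,
            )
        return np.sort(tr), np.sort(va)

    def fit(self, table: AnnotationTable, labels: Mapping[str, object] | pd.Series):
        if isinstance(labels, pd.Series):
            labels = labels.to_dict()
        rater_ids = table.rater_ids
        if not rater_ids:
            raise ValueError("annotation table has no raters")

        nested: dict[str, RaterModel] = {}
        val_sets: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
        full_data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for rid in rater_ids:
            X, _, child_ids = encode_matrix(table, rid)
            y = np.array([labels[c] for c in child_ids])
            full_data[rid] = (X, y)
            tr, va = self._split(child_ids, y)
            config = self._rf_config()
            if self.tune:
                config = self._tune_config(X[tr], y[tr], X[va], y[va])
            model = _fit_rater_forest(rid, X[tr], y[tr], config, self.random_state)
            acc = float(np.mean(model.predict(X[va]) == y[va]))
            model.validation_accuracy = acc
            nested[rid] = model
            val_sets[rid] = (X[va], y[va], [child_ids[i] for i in va])

        self.classes_ = np.unique(np.array(list(labels.values()), dtype=object))
        prevalence = pd.Series(list(labels.values())).value_counts().to_dict()

        # accuracy deltas against the majority-vote baseline, per rater's val set
        z = []
        for rid in rater_ids:
            X_va, y_va, va_children = val_sets[rid]
            y_model = nested[rid].predict(X_va)
            y_base = self._baseline_labels(nested, table, va_children, prevalence)
            z.append(accuracy_delta(y_va, y_model, y_base))
        self.z_ = np.array(z)
        self.weights_ = softmax_weights(self.z_, rater_ids, temperature=self.temperature)

        if self.refit_full:
            self.models_ = {}
            for rid in rater_ids:
                X, y = full_data[rid]
                m = _fit_rater_forest(
                    rid, X, y, nested[rid].config, self.random_state,
                    validation_accuracy=nested[rid].validation_accuracy,
                )
                self.models_[rid] = m
        else:
            self.models_ = nested
        self.rater_ids_ = list(rater_ids)
        return self

    def _baseline_labels(self, models, table, children, prevalence):
        if self.baseline == "majority_class":
            top = max(prevalence, key=lambda c: (prevalence[c], str(c)))
            return np.array([top] * len(children))
        if self.baseline != "plurality":
            raise ValueError(f"unknown baseline {self.baseline!r}")
        votes: dict[str, list] = {c: [] for c in children}
        wanted = set(children)
        for rid, m in models.items():
            rows = table.df[table.df["rater_id"] == rid]
            rows = rows[rows["child_id"].isin(wanted)].sort_values("child_id")
            if rows.empty:
                continue
            X = rows[table.vocabulary.question_ids].to_numpy(dtype=np.int64)
            preds = m.predict(X)
            for c, p in zip(rows["child_id"], preds):
                votes[c].append(p)
        consensus = majority_vote(votes, prevalence=prevalence, class_order=sorted(prevalence))
        return consensus.loc[list(children)].to_numpy()

    def _tune_config(self, X_tr, y_tr, X_va, y_va) -> dict:
        best, best_acc = self._rf_config(), -1.0
        sampler = ParameterSampler(
            _TUNE_SPACE, n_iter=self.n_tune_iter, random_state=self.random_state
        )
        for cand in sampler:
            config = {**self._rf_config(), **cand}
            try:
                m = _fit_rater_forest("tune", X_tr, y_tr, config, self.random_state)
            except ValueError:
                continue
            acc = float(np.mean(m.predict(X_va) == y_va))
            if acc > best_acc:
                best, best_acc = config, acc
        return best

    # -- prediction --------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "models_"):
            raise RuntimeError("estimator is not fitted")

    def predict_proba(self, table: AnnotationTable) -> pd.DataFrame:
        """Per-child ensemble class probabilities (children × classes)."""
        self._check_fitted()
        cols = {}
        for cls in self.classes_:
            cols[cls] = ensemble_predict(
                list(self.models_.values()), self.weights_, table, cls
            )["ensemble"]
        # columns sum to 1 by construction: sum_c sum_j w_j p_jc = sum_j w_j
        return pd.DataFrame(cols)

    def predict(self, table: AnnotationTable) -> pd.Series:
        proba = self.predict_proba(table)
        return proba.idxmax(axis=1)

    def predict_contributions(self, table: AnnotationTable, target_class) -> pd.DataFrame:
        """Ensemble probability with per-rater probabilities and used weights."""
        self._check_fitted()
        return ensemble_predict(list(self.models_.values()), self.weights_, table, target_class)

    def score(self, table: AnnotationTable, labels: Mapping[str, object]) -> float:
        pred = self.predict(table)
        y = np.array([labels[c] for c in pred.index])
        return float(np.mean(pred.to_numpy() == y))
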