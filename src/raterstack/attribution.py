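"""Shapley-value feature attribution for tree models and their ensembles.

Attribution is interventional: for a sample x, a background (reference) row
z and a feature coalition S, the game value is v(S) = f(x_S, z_{S-bar}) —
the model evaluated with the coalition's features taken from x and the rest
from z — averaged over the reference set. For decision trees this game is
computed exactly: each leaf's indicator factorizes over the features on its
path, so per (x, z) pair the leaf's game is a unanimity-style game with a
closed-form Shapley solution. Summing over leaves and trees gives exact
Shapley values in time polynomial in the number of leaves, with no subset
enumeration.

Local accuracy holds by construction: for every sample,
base + sum_k phi_k = f(x), where base is the mean predicted target-class
probability over the reference set. Because the rater ensemble is a convex
combination of tree models, ensemble Shapley values are the same weighted
combination of per-model values (linearity), with the weighted base value.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from .ensemble import RaterModel, WeightVector

__all__ = [
    "AttributionMatrix",
    "EnsembleAttribution",
    "ImportanceRanking",
    "model_shapley",
    "exact_shapley_oracle",
    "ensemble_shapley",
    "global_importance",
    "sampling_shapley",
]


@dataclass
class AttributionMatrix:
    """Per-(sample, feature) Shapley values for one model.

    ``base_value`` is the mean predicted target-class probability over the
    reference set; ``values[i].sum() + base_value`` equals the model's
    prediction for sample i (local accuracy).
    """

    model_id: str
    base_value: float
    values: np.ndarray  # (n_samples, n_features)
    predictions: np.ndarray  # (n_samples,) model's target-class probabilities
    child_ids: list[str] | None = None

    def local_accuracy_residual(self) -> float:
        return float(
            np.abs(self.base_value + self.values.sum(axis=1) - self.predictions).max()
        )


@dataclass
class EnsembleAttribution:
    """Weight-propagated ensemble Shapley values: phi = sum_j w_j phi_j."""

    weights: WeightVector
    base_value: float
    values: np.ndarray
    predictions: np.ndarray
    child_ids: list[str] | None = None

    def local_accuracy_residual(self) -> float:
        return float(
            np.abs(self.base_value + self.values.sum(axis=1) - self.predictions).max()
        )


@dataclass(frozen=True)
class ImportanceRanking:
    """Features ranked by the sum over samples of |phi|, ties by feature order."""

    scores: np.ndarray  # per feature, original order
    order: np.ndarray  # feature indices, most important first
    feature_names: tuple[str, ...] | None = None

    def as_series(self) -> pd.Series:
        names = (
            list(self.feature_names)
            if self.feature_names
            else [f"f{i}" for i in range(len(self.scores))]
        )
        return pd.Series(self.scores[self.order], index=[names[i] for i in self.order])


# ---------------------------------------------------------------------------
# Exact interventional Shapley for a single decision tree
# ---------------------------------------------------------------------------

def _shapley_coefficient_tables(cmax: int) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form per-leaf coefficients.

    For a leaf whose path splits x and z into u features satisfied only by x
    and d only by z, the leaf's game is v(S) = 1 iff all u are in S and no d
    is. Its Shapley solution: each of the u features gets
    (u-1)! d! / (u+d)! and each of the d features gets -u! (d-1)! / (u+d)!.
    """
    wp = np.zeros((cmax + 1, cmax + 1))
    wn = np.zeros((cmax + 1, cmax + 1))
    for u in range(cmax + 1):
        for d in range(cmax + 1):
            if u >= 1:
                wp[u, d] = np.exp(lgamma(u) + lgamma(d + 1) - lgamma(u + d + 1))
            if d >= 1:
                wn[u, d] = np.exp(lgamma(u + 1) + lgamma(d) - lgamma(u + d + 1))
    return wp, wn


def _leaf_table(tree) -> list[tuple[np.ndarray, np.ndarray, np.ndarray, float]]:
    """Per leaf: (feature indices, lower bounds, upper bounds, leaf value).

    Bounds encode the path constraints low < x[f] <= high, with repeated
    splits on a feature collapsed to a single interval.
    """
    t = tree.tree_
    leaves = []

    def recurse(node: int, constraints: dict[int, list[float]]) -> None:
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:  # leaf
            if constraints:
                feats = np.array(sorted(constraints), dtype=np.int64)
                lows = np.array([constraints[f][0] for f in feats])
                highs = np.array([constraints[f][1] for f in feats])
            else:
                feats = np.empty(0, dtype=np.int64)
                lows = highs = np.empty(0)
            leaves.append((feats, lows, highs, node))
            return
        f, thr = int(t.feature[node]), float(t.threshold[node])
        lo, hi = constraints.get(f, [-np.inf, np.inf])
        constraints[f] = [lo, min(hi, thr)]
        recurse(left, constraints)
        constraints[f] = [max(lo, thr), hi]
        recurse(right, constraints)
        if lo == -np.inf and hi == np.inf:
            del constraints[f]
        else:
            constraints[f] = [lo, hi]

    recurse(0, {})
    return leaves


def _tree_values(tree, target_index: int) -> np.ndarray:
    """Per-node predicted probability of the target class."""
    v = tree.tree_.value  # (n_nodes, 1, n_classes); proportions in sklearn >= 1.4
    v = v[:, 0, :]
    totals = v.sum(axis=1, keepdims=True)
    return (v / np.where(totals == 0, 1.0, totals))[:, target_index]


def _tree_shapley(tree, target_index: int, X: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Exact interventional Shapley values for one fitted decision tree."""
    n, p = X.shape
    m = Z.shape[0]
    node_value = _tree_values(tree, target_index)
    phi = np.zeros((n, p))
    wp, wn = _shapley_coefficient_tables(p)

    for feats, lows, highs, node in _leaf_table(tree):
        v = node_value[node]
        if v == 0.0 or feats.size == 0:
            continue
        A = (X[:, feats] > lows) & (X[:, feats] <= highs)  # (n, c)
        B = (Z[:, feats] > lows) & (Z[:, feats] <= highs)  # (m, c)
        only_x = A[:, None, :] & ~B[None, :, :]  # (n, m, c)
        only_z = ~A[:, None, :] & B[None, :, :]
        # a feature violated by both x and z kills the leaf for that pair
        dead = (~A[:, None, :] & ~B[None, :, :]).any(axis=2)
        u = only_x.sum(axis=2)
        d = only_z.sum(axis=2)
        live = np.where(dead, 0.0, v)
        coef_pos = (live * wp[u, d])[:, :, None]
        coef_neg = (live * wn[u, d])[:, :, None]
        contrib = only_x * coef_pos - only_z * coef_neg  # (n, m, c)
        phi[:, feats] += contrib.mean(axis=1)
    return phi


def _unwrap(model):
    if isinstance(model, RaterModel):
        return model.estimator, model.rater_id
    return model, type(model).__name__


def model_shapley(
    model,
    X: np.ndarray,
    reference: np.ndarray,
    target_class,
    max_reference: int | None = None,
    seed: int = 0,
) -> AttributionMatrix:
    """Exact interventional Shapley values for a tree or forest classifier.

    ``reference`` supplies the background distribution; the base value is the
    mean predicted target-class probability over it. ``max_reference``
    optionally subsamples the reference (seeded) to bound runtime.
    """
    est, model_id = _unwrap(model)
    X = np.asarray(X, dtype=float)
    Z = np.asarray(reference, dtype=float)
    if Z.shape[0] == 0:
        raise ValueError("reference set must be non-empty")
    if X.shape[1] != Z.shape[1]:
        raise ValueError("X and reference disagree on feature count")
    n_feat = getattr(est, "n_features_in_", X.shape[1])
    if X.shape[1] != n_feat:
        raise ValueError(
            f"model expects {n_feat} features, got {X.shape[1]}"
        )
    if max_reference is not None and Z.shape[0] > max_reference:
        rng = np.random.default_rng(seed)
        Z = Z[rng.choice(Z.shape[0], size=max_reference, replace=False)]

    classes = list(est.classes_)
    if target_class not in classes:
        raise ValueError(f"unknown target class {target_class!r}")
    ti = classes.index(target_class)

    if isinstance(est, RandomForestClassifier):
        trees = est.estimators_
        phi = np.zeros(X.shape)
        for t in trees:
            phi += _tree_shapley(t, ti, X, Z)
        phi /= len(trees)
    elif isinstance(est, DecisionTreeClassifier):
        phi = _tree_shapley(est, ti, X, Z)
    else:
        # sampling approximation for non-tree models
        phi = sampling_shapley(lambda A: est.predict_proba(A)[:, ti], X, Z, seed=seed)

    base = float(est.predict_proba(Z)[:, ti].mean())
    preds = est.predict_proba(X)[:, ti]
    return AttributionMatrix(
        model_id=model_id, base_value=base, values=phi, predictions=preds
    )


# ---------------------------------------------------------------------------
# Independent oracles / fallbacks
# ---------------------------------------------------------------------------

def exact_shapley_oracle(
    model_or_fn,
    x: np.ndarray,
    reference: np.ndarray,
    target_class=None,
) -> np.ndarray:
    """Brute-force Shapley values by enumeration over all feature subsets.

    v(S) is the model's mean prediction with features in S taken from ``x``
    and the rest substituted from each reference row. Limited to <= 12
    features; intended as a test oracle, not a production path.
    """
    x = np.asarray(x, dtype=float).ravel()
    Z = np.asarray(reference, dtype=float)
    p = x.size
    if p > 12:
        raise ValueError("oracle limited to 12 features")
    if callable(model_or_fn) and not hasattr(model_or_fn, "predict_proba"):
        predict = model_or_fn
    else:
        est, _ = _unwrap(model_or_fn)
        ti = list(est.classes_).index(target_class)
        predict = lambda A: est.predict_proba(A)[:, ti]

    m = Z.shape[0]
    n_subsets = 1 << p
    # batch-evaluate v(S) for every subset
    masks = ((np.arange(n_subsets)[:, None] >> np.arange(p)[None, :]) & 1).astype(bool)
    big = np.where(np.repeat(masks, m, axis=0), x[None, :], np.tile(Z, (n_subsets, 1)))
    fv = np.asarray(predict(big), dtype=float).reshape(n_subsets, m).mean(axis=1)

    sizes = masks.sum(axis=1)
    fact = np.array([np.exp(lgamma(i + 1)) for i in range(p + 1)])
    phi = np.zeros(p)
    for k in range(p):
        without = ~masks[:, k]
        s_idx = np.flatnonzero(without)
        s_sizes = sizes[s_idx]
        weights = fact[s_sizes] * fact[p - s_sizes - 1] / fact[p]
        v_with = fv[s_idx | (1 << k)]
        phi[k] = float(np.sum(weights * (v_with - fv[s_idx])))
    return phi


def sampling_shapley(
    predict: Callable[[np.ndarray], np.ndarray],
    X: np.ndarray,
    reference: np.ndarray,
    n_permutations: int = 2048,
    seed: int = 0,
) -> np.ndarray:
    """Permutation-sampling Shapley estimate for arbitrary models.

    For each sampled permutation and reference row, features are switched
    from the reference value to the sample value in permutation order; the
    successive prediction differences are unbiased marginal contributions.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.asarray(reference, dtype=float)
    rng = np.random.default_rng(seed)
    n, p = X.shape
    phi = np.zeros((n, p))
    for _ in range(n_permutations):
        perm = rng.permutation(p)
        z = Z[rng.integers(Z.shape[0])]
        cur = np.tile(z, (n, 1))
        prev = np.asarray(predict(cur), dtype=float)
        for f in perm:
            cur[:, f] = X[:, f]
            nxt = np.asarray(predict(cur), dtype=float)
            phi[:, f] += nxt - prev
            prev = nxt
    return phi / n_permutations


def ensemble_shapley(
    per_model: Sequence[AttributionMatrix], weights: WeightVector
) -> EnsembleAttribution:
    """Weighted sum of per-model attributions: phi_ens = sum_j w_j phi_j."""
    if len(per_model) != len(weights.rater_ids):
        raise ValueError("one attribution matrix per weighted rater is required")
    shape = per_model[0].values.shape
    ids0 = per_model[0].child_ids
    for am in per_model[1:]:
        if am.values.shape != shape:
            raise ValueError("attribution matrices are misaligned in shape")
        if am.child_ids != ids0:
            raise ValueError("attribution matrices are misaligned on samples")
    w = weights.w
    values = sum(wj * am.values for wj, am in zip(w, per_model))
    base = float(sum(wj * am.base_value for wj, am in zip(w, per_model)))
    preds = sum(wj * am.predictions for wj, am in zip(w, per_model))
    return EnsembleAttribution(
        weights=weights,
        base_value=base,
        values=np.asarray(values),
        predictions=np.asarray(preds),
        child_ids=ids0,
    )


def global_importance(
    attr: EnsembleAttribution | AttributionMatrix,
    feature_names: Sequence[str] | None = None,
) -> ImportanceRanking:
    """Rank features by the sum over samples of absolute Shapley values."""
    values = attr.values
    if values.shape[0] < 1:
        raise ValueError("need at least one sample")
    scores = np.abs(values).sum(axis=0)
    order = np.argsort(-scores, kind="stable")  # ties keep feature order
    return ImportanceRanking(
        scores=scores,
        order=order,
        feature_names=tuple(feature_names) if feature_names is not None else None,
    )
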