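"""Two-layer stacked screening with cross-validated metric reporting.

Layer 1 separates typical development (TD) from atypical development
(ASD or SLC). Children the layer-1 ensemble scores at or above the decision
threshold are gated into layer 2, which separates ASD from other delays.
Layer 2 is trained on the truly atypical training children but evaluated on
the gated (predicted-atypical) test children, so a TD false positive from
layer 1 is scored as a layer-2 negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .data import AnnotationTable, FoldAssignment
from .ensemble import RaterEnsembleClassifier

__all__ = [
    "LayerSpec",
    "MetricsReport",
    "binarize_labels",
    "gate_atypical",
    "compute_metrics",
    "evaluate_stack_cv",
    "StackedScreeningClassifier",
]

METRICS = ("sensitivity", "specificity", "uar", "auc", "accuracy")


@dataclass(frozen=True)
class LayerSpec:
    """Layer id and decision threshold on the ensemble probability.

    Layer 1: positive class is atypical development (ASD or SLC).
    Layer 2: positive class is ASD.
    """

    layer: int
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.layer not in (1, 2):
            raise ValueError("layer must be 1 or 2")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly between 0 and 1")


def binarize_labels(diagnoses: Sequence[str] | pd.Series, layer: int) -> np.ndarray:
    """Layer 1: TD -> 0, ASD/SLC -> 1. Layer 2: ASD -> 1, SLC/TD -> 0."""
    diag = np.asarray(diagnoses, dtype=object)
    known = {"TD", "SLC", "ASD"}
    bad = set(diag) - known
    if bad:
        raise ValueError(f"unknown diagnoses: {sorted(bad)}")
    if layer == 1:
        return (diag != "TD").astype(int)
    if layer == 2:
        return (diag == "ASD").astype(int)
    raise ValueError("layer must be 1 or 2")


def gate_atypical(probabilities: pd.Series, threshold: float) -> list[str]:
    """Children whose layer-1 ensemble probability is >= threshold."""
    return sorted(probabilities.index[probabilities >= threshold])


def compute_metrics(
    y_true: Sequence[int], scores: Sequence[float], threshold: float = 0.5
) -> dict[str, float]:
    """Single-fold binary metrics at a probability threshold.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    UAR = (sensitivity + specificity)/2, accuracy = (TP+TN)/n,
    AUC by the rank statistic with tie correction (Mann-Whitney).
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if y_true.size == 0:
        raise ValueError("empty evaluation set")
    if len(np.unique(y_true)) < 2:
        raise ValueError(
            "single-class truth: AUC, sensitivity and specificity are undefined"
        )
    y_pred = (scores >= threshold).astype(int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "uar": (sens + spec) / 2.0,
        "auc": float(roc_auc_score(y_true, scores)),
        "accuracy": (tp + tn) / y_true.size,
    }


@dataclass
class MetricsReport:
    """Per-fold metric values with mean and sample SD over retained folds."""

    per_fold: pd.DataFrame  # rows: fold index; columns: METRICS (NaN = undefined)

    @property
    def mean(self) -> pd.Series:
        return self.per_fold.mean(skipna=True)

    @property
    def sd(self) -> pd.Series:
        return self.per_fold.std(ddof=1, skipna=True)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.sd})

    def to_dict(self) -> dict:
        return {
            "per_fold": self.per_fold.to_dict(orient="index"),
            "mean": self.mean.to_dict(),
            "sd": self.sd.to_dict(),
        }


def _fit_layer_ensemble(table, child_ids, layer, config, seed):
    sub = table.subset(child_ids)
    labels = {c: int(v) for c, v in zip(
        sorted(child_ids), binarize_labels(table.diagnoses(sorted(child_ids)), layer)
    )}
    est = RaterEnsembleClassifier(random_state=seed, **(config or {}))
    return est.fit(sub, labels)


def evaluate_stack_cv(
    table: AnnotationTable,
    folds: FoldAssignment,
    config: dict | None = None,
    seed: int = 0,
    threshold: float = 0.5,
) -> dict[str, MetricsReport]:
    """Cross-validated evaluation of the two-layer stack.

    Per fold: train the layer-1 ensemble on the training children (TD vs
    atypical) and the layer-2 ensemble on the truly atypical training
    children (ASD vs SLC). Evaluate layer 1 on all test children; gate test
    children with layer-1 probability >= threshold into layer 2, scoring any
    gated TD child as a negative. Folds where the gated set is single-class
    get NaN layer-2 metrics (excluded from the mean) with a warning.
    """
    if folds.n_folds < 2:
        raise ValueError("need at least 2 folds")
    rows1, rows2, details = [], [], []
    for f in range(folds.n_folds):
        train_ids = folds.train_children(f)
        test_ids = folds.fold_children(f)

        ens1 = _fit_layer_ensemble(table, train_ids, layer=1, config=config, seed=seed + f)
        atypical_train = [c for c in train_ids if table.diagnosis(c) != "TD"]
        ens2 = _fit_layer_ensemble(table, atypical_train, layer=2, config=config, seed=seed + f)

        test_table = table.subset(test_ids)
        p1 = ens1.predict_proba(test_table)[1]
        y1 = binarize_labels(table.diagnoses(sorted(test_ids)), layer=1)
        m1 = compute_metrics(y1, p1.loc[sorted(test_ids)], threshold)
        rows1.append(m1)

        gated = gate_atypical(p1, threshold)
        fold_detail = {"fold": f, "p1": p1, "gated": gated}
        y2_true = binarize_labels(table.diagnoses(gated), layer=2) if gated else np.array([], int)
        if len(gated) and len(np.unique(y2_true)) == 2:
            p2 = ens2.predict_proba(table.subset(gated))[1]
            m2 = compute_metrics(y2_true, p2.loc[gated], threshold)
            fold_detail["p2"] = p2
        else:
            warnings.warn(
                f"fold {f}: layer-2 gated set is single-class; metrics undefined",
                stacklevel=2,
            )
            m2 = {m: np.nan for m in METRICS}
        rows2.append(m2)
        details.append(fold_detail)

    report = {
        "layer1": MetricsReport(pd.DataFrame(rows1, columns=list(METRICS))),
        "layer2": MetricsReport(pd.DataFrame(rows2, columns=list(METRICS))),
    }
    report["layer1"].details = details  # per-fold probabilities, for audits
    return report


class StackedScreeningClassifier:
    """Both layers trained on one dataset; three-way prediction via gating.

    ``predict`` returns TD for children below the layer-1 threshold, and
    ASD or SLC for gated children according to the layer-2 probability.
    """

    def __init__(self, threshold: float = 0.5, ensemble_config: dict | None = None,
                 random_state: int = 0) -> None:
        self.threshold = threshold
        self.ensemble_config = ensemble_config
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "threshold": self.threshold,
            "ensemble_config": self.ensemble_config,
            "random_state": self.random_state,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, table: AnnotationTable):
        ids = table.child_ids
        self.layer1_ = _fit_layer_ensemble(table, ids, 1, self.ensemble_config, self.random_state)
        atypical = [c for c in ids if table.diagnosis(c) != "TD"]
        self.layer2_ = _fit_layer_ensemble(table, atypical, 2, self.ensemble_config, self.random_state)
        return self

    def predict_proba(self, table: AnnotationTable) -> pd.DataFrame:
        """Per-child layer-1 (atypical) and layer-2 (ASD) probabilities."""
        p1 = self.layer1_.predict_proba(table)[1]
        gated = gate_atypical(p1, self.threshold)
        p2 = pd.Series(np.nan, index=p1.index)
        if gated:
            p2.loc[gated] = self.layer2_.predict_proba(table.subset(gated))[1]
        return pd.DataFrame({"p_atypical": p1, "p_asd": p2})

    def predict(self, table: AnnotationTable) -> pd.Series:
        proba = self.predict_proba(table)
        out = pd.Series("TD", index=proba.index, name="prediction")
        gated = proba["p_atypical"] >= self.threshold
        out[gated & (proba["p_asd"] >= self.threshold)] = "ASD"
        out[gated & (proba["p_asd"] < self.threshold)] = "SLC"
        return out
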