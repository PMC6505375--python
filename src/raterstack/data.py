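"""Annotation tables, child records, CSV round-trip and fold assignment.

The canonical on-disk format is a UTF-8 CSV with one row per (child, rater)
pair and columns ``child_id, rater_id, diagnosis[, site], q01..qNN``.
Answers are ordinal integer codes; an empty cell means unratable/missing and
is stored internally as the question's sentinel code.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .vocabulary import FeatureVocabulary

__all__ = [
    "DIAGNOSES",
    "ChildRecord",
    "AnnotationTable",
    "FoldAssignment",
    "read_annotations",
    "write_annotations",
    "encode_matrix",
    "assign_folds",
]

DIAGNOSES = ("TD", "SLC", "ASD")


@dataclass(frozen=True)
class ChildRecord:
    child_id: str
    diagnosis: str
    site: str | None = None

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(
                f"diagnosis for child {self.child_id!r} must be one of "
                f"{DIAGNOSES}, got {self.diagnosis!r}"
            )


class AnnotationTable:
    """Validated (child, rater) annotation rows linked to a vocabulary.

    Parameters
    ----------
    df : DataFrame with columns ``child_id``, ``rater_id`` and one integer
        column per vocabulary question (sentinel code for missing).
    vocabulary : the instrument the answer codes refer to.
    children : child_id -> ChildRecord for every child appearing in ``df``.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        vocabulary: FeatureVocabulary,
        children: Mapping[str, ChildRecord],
    ) -> None:
        qids = vocabulary.question_ids
        required = ["child_id", "rater_id", *qids]
        missing_cols = [c for c in required if c not in df.columns]
        if missing_cols:
            raise ValueError(f"annotation table missing columns: {missing_cols}")

        df = df[required].copy()
        df["child_id"] = df["child_id"].astype(str)
        df["rater_id"] = df["rater_id"].astype(str)
        dup = df.duplicated(subset=["child_id", "rater_id"])
        if dup.any():
            pair = df.loc[dup.idxmax(), ["child_id", "rater_id"]].tolist()
            raise ValueError(f"duplicate (child, rater) pair: {tuple(pair)}")

        for qid in qids:
            codes = df[qid].to_numpy()
            q = vocabulary.question(qid)
            bad = (codes < 0) | (codes > q.missing_code)
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"invalid answer code {codes[row]} for question {qid!r} "
                    f"(child {df['child_id'].iloc[row]!r}, "
                    f"rater {df['rater_id'].iloc[row]!r}): valid codes are "
                    f"0..{q.n_choices - 1} plus sentinel {q.missing_code}"
                )
            df[qid] = codes.astype(np.int64)

        unresolved = set(df["child_id"]) - set(children)
        if unresolved:
            raise ValueError(f"children without a ChildRecord: {sorted(unresolved)}")

        self.df = df.sort_values(["child_id", "rater_id"], kind="stable").reset_index(
            drop=True
        )
        self.vocabulary = vocabulary
        self.children = dict(children)

    # -- convenience accessors -------------------------------------------

    @property
    def child_ids(self) -> list[str]:
        return sorted(self.df["child_id"].unique())

    @property
    def rater_ids(self) -> list[str]:
        return sorted(self.df["rater_id"].unique())

    def diagnosis(self, child_id: str) -> str:
        return self.children[child_id].diagnosis

    def diagnoses(self, child_ids: Iterable[str] | None = None) -> pd.Series:
        ids = list(child_ids) if child_ids is not None else self.child_ids
        return pd.Series({c: self.children[c].diagnosis for c in ids}, name="diagnosis")

    def subset(self, child_ids: Iterable[str]) -> "AnnotationTable":
        """Rows (and records) restricted to the given children."""
        keep = set(child_ids)
        df = self.df[self.df["child_id"].isin(keep)]
        children = {c: r for c, r in self.children.items() if c in keep}
        return AnnotationTable(df, self.vocabulary, children)

    def __len__(self) -> int:
        return len(self.df)

    def equals(self, other: "AnnotationTable") -> bool:
        return (
            self.df.equals(other.df)
            and self.children == other.children
            and self.vocabulary == other.vocabulary
        )


def read_annotations(path, vocabulary: FeatureVocabulary) -> AnnotationTable:
    """Read and validate an annotations CSV.

    Empty answer cells are mapped to each question's missing sentinel.
    Raises ``ValueError`` naming the offending cell for out-of-range codes
    and for duplicate (child, rater) pairs.
    """
    raw = pd.read_csv(path, dtype={"child_id": str, "rater_id": str})
    qids = vocabulary.question_ids
    missing_cols = [c for c in ("child_id", "rater_id", "diagnosis", *qids) if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"CSV header missing columns: {missing_cols}")

    for qid in qids:
        sentinel = vocabulary.question(qid).missing_code
        col = pd.to_numeric(raw[qid], errors="raise")
        raw[qid] = col.fillna(sentinel).astype(np.int64)

    children = {}
    for child_id, grp in raw.groupby("child_id", sort=False):
        diag = grp["diagnosis"].unique()
        if len(diag) != 1:
            raise ValueError(f"child {child_id!r} has conflicting diagnoses: {list(diag)}")
        site = None
        if "site" in raw.columns:
            s = grp["site"].dropna().unique()
            site = str(s[0]) if len(s) else None
        children[str(child_id)] = ChildRecord(str(child_id), str(diag[0]), site)

    return AnnotationTable(raw, vocabulary, children)


def write_annotations(table: AnnotationTable, path) -> None:
    """Write the canonical CSV: sorted rows, sentinel codes as empty cells."""
    qids = table.vocabulary.question_ids
    out = table.df.copy()
    out.insert(2, "diagnosis", out["child_id"].map(lambda c: table.children[c].diagnosis))
    sites = {c: r.site for c, r in table.children.items()}
    if any(s is not None for s in sites.values()):
        out.insert(3, "site", out["child_id"].map(sites))
    for qid in qids:
        sentinel = table.vocabulary.question(qid).missing_code
        out[qid] = out[qid].astype("object")
        out.loc[out[qid] == sentinel, qid] = ""
    buf = io.StringIO()
    out.to_csv(buf, index=False, lineterminator="\n")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())


def encode_matrix(
    table: AnnotationTable, rater_id: str
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-child feature matrix for one rater.

    Returns ``(X, y, child_ids)``: one row per child rated by ``rater_id``
    in sorted child_id order, ordinal integer codes (missing sentinel passed
    through), and the aligned diagnosis labels.
    """
    rows = table.df[table.df["rater_id"] == rater_id]
    if rows.empty:
        raise ValueError(f"rater {rater_id!r} has no annotations")
    rows = rows.sort_values("child_id", kind="stable")
    child_ids = rows["child_id"].tolist()
    X = rows[table.vocabulary.question_ids].to_numpy(dtype=np.int64)
    y = np.array([table.children[c].diagnosis for c in child_ids])
    return X, y, child_ids


@dataclass(frozen=True)
class FoldAssignment:
    """Partition of children into folds, stratified by diagnosis."""

    n_folds: int
    assignment: Mapping[str, int]
    seed: int

    def fold_children(self, fold: int) -> list[str]:
        return sorted(c for c, f in self.assignment.items() if f == fold)

    def train_children(self, fold: int) -> list[str]:
        return sorted(c for c, f in self.assignment.items() if f != fold)

    def fold_sizes(self) -> list[int]:
        counts = [0] * self.n_folds
        for f in self.assignment.values():
            counts[f] += 1
        return counts


def assign_folds(children: Iterable[ChildRecord], k: int, seed: int) -> FoldAssignment:
    """Stratified fold assignment balanced on total fold size.

    Children are shuffled within diagnosis class and dealt round-robin into
    folds with a pointer that carries across classes, so total fold sizes
    differ by at most one and each fold's class mix is within one child of
    proportional. Deterministic given ``seed``.
    """
    children = list(children)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > len(children):
        raise ValueError(f"k={k} exceeds the number of children ({len(children)})")

    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    pointer = 0
    for diag in DIAGNOSES:
        ids = sorted(c.child_id for c in children if c.diagnosis == diag)
        order = rng.permutation(len(ids))
        for idx in order:
            assignment[ids[idx]] = pointer % k
            pointer += 1
    return FoldAssignment(n_folds=k, assignment=assignment, seed=seed)
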