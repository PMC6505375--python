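"""Synthetic cohorts and heterogeneous-rater annotations.

The generator emulates the statistical structure the rater-adaptive method
assumes: each child has a latent "true" answer per question drawn from a
class-conditional archetype distribution, and each rater reports that latent
answer with a per-question reliability r (otherwise a uniformly random wrong
code), or marks the question unratable with a per-question missingness
probability. Rater expertise is therefore feature-specific by construction,
which is the premise the softmax weighting scheme exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .data import DIAGNOSES, AnnotationTable, ChildRecord
from .vocabulary import (
    CORE_QUESTIONS,
    LANGUAGE_QUESTIONS,
    FeatureVocabulary,
    default_vocabulary,
)

__all__ = [
    "CohortSpec",
    "RaterProfile",
    "SiteShiftSpec",
    "Cohort",
    "generate_cohort",
    "simulate_raters",
    "generate_two_sites",
    "default_archetypes",
    "null_archetypes",
    "separable_archetypes",
    "default_profiles",
    "default_cohort_spec",
    "scenario_from_yaml",
    "scenario_to_yaml",
]

_PROB_TOL = 1e-9


def _validate_archetype(arch: np.ndarray, vocabulary: FeatureVocabulary, label: str) -> None:
    if arch.shape[0] != len(vocabulary):
        raise ValueError(f"archetype for {label} has {arch.shape[0]} questions, expected {len(vocabulary)}")
    if (arch < 0).any():
        raise ValueError(f"archetype for {label} has negative probabilities")
    sums = arch.sum(axis=1)
    if np.abs(sums - 1.0).max() > _PROB_TOL:
        q = int(np.abs(sums - 1.0).argmax())
        raise ValueError(
            f"archetype for {label}, question index {q}: probabilities sum to {sums[q]!r}, not 1"
        )


@dataclass
class CohortSpec:
    """Class counts plus per-class, per-question answer-code distributions.

    ``archetypes`` maps each diagnosis to an array of shape
    ``(n_questions, n_codes)`` whose rows are probability vectors over the
    non-missing answer codes.
    """

    n_asd: int
    n_slc: int
    n_td: int
    archetypes: Mapping[str, np.ndarray]
    seed: int = 0
    vocabulary: FeatureVocabulary = field(default_factory=default_vocabulary)

    def __post_init__(self) -> None:
        for n, name in ((self.n_asd, "n_asd"), (self.n_slc, "n_slc"), (self.n_td, "n_td")):
            if n < 0:
                raise ValueError(f"{name} must be non-negative")
        for diag in DIAGNOSES:
            if diag not in self.archetypes:
                raise ValueError(f"missing archetype for class {diag!r}")
            self.archetypes = dict(self.archetypes)
            self.archetypes[diag] = np.asarray(self.archetypes[diag], dtype=float)
            _validate_archetype(self.archetypes[diag], self.vocabulary, diag)

    @property
    def n_total(self) -> int:
        return self.n_asd + self.n_slc + self.n_td

    def counts(self) -> dict[str, int]:
        return {"ASD": self.n_asd, "SLC": self.n_slc, "TD": self.n_td}


@dataclass
class RaterProfile:
    """Per-question reliability and missingness for one simulated rater.

    ``reliability[q]`` is the probability the rater reports the child's
    latent answer for question q; with the complementary probability the
    report is uniform over the remaining (wrong) codes. ``missingness[q]``
    is the probability of emitting the unratable sentinel instead.
    """

    rater_id: str
    reliability: np.ndarray
    missingness: np.ndarray

    def __post_init__(self) -> None:
        self.reliability = np.asarray(self.reliability, dtype=float)
        self.missingness = np.asarray(self.missingness, dtype=float)
        for arr, name in ((self.reliability, "reliability"), (self.missingness, "missingness")):
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError(f"{name} for rater {self.rater_id!r} must lie in [0, 1]")


@dataclass
class SiteShiftSpec:
    """Distribution shift applied to a subset of questions at the second site.

    Each shifted question's class archetypes are blended toward the uniform
    distribution: ``p_B = (1 - magnitude) * p_A + magnitude * uniform``.
    At magnitude 1 the shifted questions carry no class signal at site B.
    """

    questions: Sequence[int]
    magnitude: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.magnitude <= 1.0:
            raise ValueError("shift magnitude must lie in [0, 1]")


@dataclass
class Cohort:
    """Generated children plus their latent true-answer matrix."""

    children: list[ChildRecord]
    latent: np.ndarray  # (n_children, n_questions) integer codes
    vocabulary: FeatureVocabulary

    @property
    def child_ids(self) -> list[str]:
        return [c.child_id for c in self.children]


def generate_cohort(spec: CohortSpec, site: str | None = None, id_prefix: str = "C") -> Cohort:
    """Draw a cohort: latent answers sampled from each class's archetype."""
    rng = np.random.default_rng(spec.seed)
    vocab = spec.vocabulary
    n_q = len(vocab)

    children: list[ChildRecord] = []
    rows: list[np.ndarray] = []
    idx = 0
    for diag in DIAGNOSES:  # fixed class order for reproducibility
        arch = spec.archetypes[diag]
        for _ in range(spec.counts()[diag]):
            idx += 1
            cid = f"{id_prefix}{idx:04d}"
            children.append(ChildRecord(cid, diag, site))
            answers = np.array(
                [rng.choice(arch.shape[1], p=arch[q]) for q in range(n_q)],
                dtype=np.int64,
            )
            rows.append(answers)
    latent = np.vstack(rows) if rows else np.zeros((0, n_q), dtype=np.int64)
    return Cohort(children=children, latent=latent, vocabulary=vocab)


def simulate_raters(
    cohort: Cohort, profiles: Sequence[RaterProfile], seed: int
) -> AnnotationTable:
    """Generate the (child, rater) annotation table from rater noise models."""
    if not profiles:
        raise ValueError("at least one rater profile is required")
    vocab = cohort.vocabulary
    n_q = len(vocab)
    n_choices = np.array([q.n_choices for q in vocab.questions])
    sentinels = np.array([q.missing_code for q in vocab.questions])

    rng = np.random.default_rng(seed)
    records = []
    for prof in profiles:
        if prof.reliability.shape != (n_q,) or prof.missingness.shape != (n_q,):
            raise ValueError(
                f"profile for {prof.rater_id!r} must have one reliability and "
                f"missingness entry per question ({n_q})"
            )
        for child, latent in zip(cohort.children, cohort.latent):
            u_miss = rng.random(n_q)
            u_rel = rng.random(n_q)
            # wrong answer: uniform over the other codes, via an offset 1..n-1
            offsets = rng.integers(1, n_choices)  # n_choices >= 2 guaranteed
            wrong = (latent + offsets) % n_choices
            ans = np.where(u_rel < prof.reliability, latent, wrong)
            ans = np.where(u_miss < prof.missingness, sentinels, ans)
            records.append((child.child_id, prof.rater_id, *ans))

    import pandas as pd

    df = pd.DataFrame(records, columns=["child_id", "rater_id", *vocab.question_ids])
    children = {c.child_id: c for c in cohort.children}
    return AnnotationTable(df, vocab, children)


def _shift_archetypes(
    archetypes: Mapping[str, np.ndarray], shift: SiteShiftSpec
) -> dict[str, np.ndarray]:
    shifted = {}
    for diag, arch in archetypes.items():
        arch = np.asarray(arch, dtype=float).copy()
        for q in shift.questions:
            uniform = np.full(arch.shape[1], 1.0 / arch.shape[1])
            arch[q] = (1.0 - shift.magnitude) * arch[q] + shift.magnitude * uniform
        shifted[diag] = arch
    return shifted


def generate_two_sites(
    spec: CohortSpec, shift: SiteShiftSpec, seed_b: int | None = None
) -> tuple[Cohort, Cohort]:
    """Site A from the base archetypes, site B from the shifted archetypes.

    Sites use disjoint sampling streams (site B's seed defaults to
    ``spec.seed + 1``) and tag their ChildRecords with the site name.
    """
    spec_b = CohortSpec(
        n_asd=spec.n_asd,
        n_slc=spec.n_slc,
        n_td=spec.n_td,
        archetypes=_shift_archetypes(spec.archetypes, shift),
        seed=spec.seed + 1 if seed_b is None else seed_b,
        vocabulary=spec.vocabulary,
    )
    site_a = generate_cohort(spec, site="A", id_prefix="A")
    site_b = generate_cohort(spec_b, site="B", id_prefix="B")
    return site_a, site_b


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

def _severity_archetype(mu: np.ndarray, n_codes: int = 4, tau: float = 0.7) -> np.ndarray:
    """Per-question answer distributions peaked at mean severity ``mu``.

    p(code) proportional to exp(-|code - mu| / tau): a simple ordinal noise
    kernel that keeps neighbouring severities plausible.
    """
    codes = np.arange(n_codes)
    logits = -np.abs(codes[None, :] - mu[:, None]) / tau
    p = np.exp(logits)
    return p / p.sum(axis=1, keepdims=True)


def default_archetypes(
    vocabulary: FeatureVocabulary | None = None, tau: float = 0.7
) -> dict[str, np.ndarray]:
    """Moderately separated class archetypes.

    ASD children skew severe on the core social-communication/repetitive
    items and mildly on language items; SLC children skew severe on language
    items; TD children stay near the typical end everywhere. Items outside
    the two signal blocks are class-uninformative.
    """
    vocab = vocabulary or default_vocabulary()
    n_q = len(vocab)

    def mus(core: float, lang: float, rest: float = 0.5) -> np.ndarray:
        mu = np.full(n_q, rest)
        mu[list(CORE_QUESTIONS)] = core
        mu[list(LANGUAGE_QUESTIONS)] = lang
        return mu

    return {
        "TD": _severity_archetype(mus(core=0.4, lang=0.4), tau=tau),
        "SLC": _severity_archetype(mus(core=0.9, lang=2.3), tau=tau),
        "ASD": _severity_archetype(mus(core=2.3, lang=1.5), tau=tau),
    }


def null_archetypes(vocabulary: FeatureVocabulary | None = None) -> dict[str, np.ndarray]:
    """Identical archetypes for all classes: zero class signal."""
    vocab = vocabulary or default_vocabulary()
    base = _severity_archetype(np.full(len(vocab), 1.0))
    return {diag: base.copy() for diag in DIAGNOSES}


def separable_archetypes(vocabulary: FeatureVocabulary | None = None) -> dict[str, np.ndarray]:
    """Point-mass archetypes: classes are perfectly separable from any rating."""
    vocab = vocabulary or default_vocabulary()
    n_q = len(vocab)

    def point_mass(code: int) -> np.ndarray:
        arch = np.zeros((n_q, 4))
        arch[:, code] = 1.0
        return arch

    return {"TD": point_mass(0), "SLC": point_mass(2), "ASD": point_mass(3)}


def default_profiles(
    vocabulary: FeatureVocabulary | None = None, missingness: float = 0.02
) -> list[RaterProfile]:
    """Three heterogeneous raters: reliable, feature-complementary, near-chance.

    R1 is reliable everywhere (r = 0.95). R2 has complementary expertise:
    weak (r = 0.35) on the core social-communication items but reliable
    (r = 0.75) on the language and general items. R3 is near chance
    everywhere (r = 0.40).
    """
    vocab = vocabulary or default_vocabulary()
    n_q = len(vocab)
    r2 = np.full(n_q, 0.75)
    r2[list(CORE_QUESTIONS)] = 0.35
    miss = np.full(n_q, missingness)
    return [
        RaterProfile("R1", np.full(n_q, 0.95), miss.copy()),
        RaterProfile("R2", r2, miss.copy()),
        RaterProfile("R3", np.full(n_q, 0.40), miss.copy()),
    ]


def default_cohort_spec(
    n_total: int = 159,
    seed: int = 0,
    archetypes: Mapping[str, np.ndarray] | None = None,
    vocabulary: FeatureVocabulary | None = None,
) -> CohortSpec:
    """Cohort spec with the study's 55/50/54 ASD/SLC/TD mix, rescaled to n_total."""
    vocab = vocabulary or default_vocabulary()
    base = {"ASD": 55, "SLC": 50, "TD": 54}
    total = sum(base.values())
    counts = {d: int(round(n * n_total / total)) for d, n in base.items()}
    # fix rounding drift on the largest class
    counts["ASD"] += n_total - sum(counts.values())
    return CohortSpec(
        n_asd=counts["ASD"],
        n_slc=counts["SLC"],
        n_td=counts["TD"],
        archetypes=archetypes or default_archetypes(vocab),
        seed=seed,
        vocabulary=vocab,
    )


# ---------------------------------------------------------------------------
# Scenario YAML round-trip (CLI surface)
# ---------------------------------------------------------------------------

def scenario_to_yaml(spec: CohortSpec, profiles: Sequence[RaterProfile], path) -> None:
    doc = {
        "counts": spec.counts(),
        "seed": spec.seed,
        "archetypes": {d: spec.archetypes[d].tolist() for d in DIAGNOSES},
        "raters": [
            {
                "rater_id": p.rater_id,
                "reliability": p.reliability.tolist(),
                "missingness": p.missingness.tolist(),
            }
            for p in profiles
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def scenario_from_yaml(path, vocabulary: FeatureVocabulary | None = None):
    vocab = vocabulary or default_vocabulary()
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    spec = CohortSpec(
        n_asd=doc["counts"]["ASD"],
        n_slc=doc["counts"]["SLC"],
        n_td=doc["counts"]["TD"],
        archetypes={d: np.asarray(a) for d, a in doc["archetypes"].items()},
        seed=doc.get("seed", 0),
        vocabulary=vocab,
    )
    profiles = [
        RaterProfile(r["rater_id"], np.asarray(r["reliability"]), np.asarray(r["missingness"]))
        for r in doc["raters"]
    ]
    return spec, profiles
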