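"""Feature vocabulary: the multiple-choice behavioral instrument.

Each question has an ordered list of answer choices encoded as ordinal
integers starting at 0 (choices are severity-ordered), plus a per-question
missing/"unratable" sentinel equal to ``len(answers)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

__all__ = ["Question", "FeatureVocabulary", "default_vocabulary"]


@dataclass(frozen=True)
class Question:
    """One instrument item: an id, a display name and ordered answer labels."""

    id: str
    name: str
    answers: tuple[str, ...]

    @property
    def n_choices(self) -> int:
        return len(self.answers)

    @property
    def missing_code(self) -> int:
        """Sentinel code for an unratable/missing answer (max code + 1)."""
        return len(self.answers)


@dataclass(frozen=True)
class FeatureVocabulary:
    """Ordered collection of questions defining the annotation feature space."""

    questions: tuple[Question, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        ids = [q.id for q in self.questions]
        if len(set(ids)) != len(ids):
            raise ValueError("question ids must be unique")
        names = [q.name for q in self.questions]
        if len(set(names)) != len(names):
            raise ValueError("question names must be unique")
        for q in self.questions:
            if q.n_choices < 2:
                raise ValueError(f"question {q.id!r} needs at least 2 answer choices")

    def __len__(self) -> int:
        return len(self.questions)

    @property
    def question_ids(self) -> list[str]:
        return [q.id for q in self.questions]

    @property
    def names(self) -> list[str]:
        return [q.name for q in self.questions]

    def question(self, qid: str) -> Question:
        for q in self.questions:
            if q.id == qid:
                return q
        raise KeyError(f"unknown question id {qid!r}")

    def index(self, qid: str) -> int:
        return self.question_ids.index(qid)

    def valid_codes(self, qid: str) -> range:
        """Valid integer codes for a question, including the missing sentinel."""
        q = self.question(qid)
        return range(q.n_choices + 1)

    def to_yaml(self, path) -> None:
        doc = {
            q.id: {"name": q.name, "answers": list(q.answers)} for q in self.questions
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)

    @classmethod
    def from_yaml(cls, path) -> "FeatureVocabulary":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        qs = tuple(
            Question(id=qid, name=spec["name"], answers=tuple(spec["answers"]))
            for qid, spec in doc.items()
        )
        return cls(questions=qs)


_SEVERITY_ANSWERS = (
    "typical / clearly present",
    "mildly atypical",
    "moderately atypical",
    "markedly atypical / absent",
)

# 31 behavioral items. The first block names core social-communication and
# restricted/repetitive behaviors; the middle block names language items;
# the remainder are general behavioral items. Severity-ordered choices.
_DEFAULT_NAMES = (
    # core autism-associated behaviors
    "eye contact",
    "stereotyped interests and actions",
    "sensory seeking",
    "calls attention to objects",
    "responsiveness",
    "social participation",
    "stereotyped speech",
    "repetitive movements",
    "joint attention",
    "pointing to express interest",
    # language-related behaviors
    "understands language",
    "speech clarity",
    "vocabulary range",
    "sentence complexity",
    "follows instructions",
    "conversational turn-taking",
    # general behavioral items
    "responds to name",
    "imitation",
    "pretend play",
    "use of gestures",
    "facial expressions",
    "shows objects to others",
    "social smiling",
    "interest in peers",
    "insistence on sameness",
    "unusual attachments to objects",
    "emotional expression",
    "variety of play",
    "activity level",
    "frustration tolerance",
    "gaze shifting between people and objects",
)

# Index sets used by the synthetic-data archetypes.
CORE_QUESTIONS = tuple(range(0, 10))
LANGUAGE_QUESTIONS = tuple(range(10, 16))


def default_vocabulary() -> FeatureVocabulary:
    """The default 31-question instrument with 4 severity-ordered choices each."""
    qs = tuple(
        Question(id=f"q{i + 1:02d}", name=name, answers=_SEVERITY_ANSWERS)
        for i, name in enumerate(_DEFAULT_NAMES)
    )
    return FeatureVocabulary(questions=qs)
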