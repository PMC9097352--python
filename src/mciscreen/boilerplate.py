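"""Cross-patient boilerplate detection.

EHR systems propagate template text ("smart phrases", after-visit summaries,
medication-reminder blurbs) into many patients' notes.  A dictionary match
inside such a template says nothing about the patient, so mentions whose
surrounding text is shared with other patients are flagged and excluded from
feature construction.  Sharing is defined on the mention's context windows:
a mention is boilerplate when its preceding 180 characters OR following 180
characters (exact string, whitespace-trimmed) also occur as the context of a
mention from at least one other patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from sklearn.base import BaseEstimator, TransformerMixin

from .text_matcher import ConceptMention


def _normalize(context: str) -> str:
    return context.strip()


@dataclass
class ContextIndex:
    """Who produced each context string, kept separately for each side."""

    left: dict[str, set[str]] = field(default_factory=dict)
    right: dict[str, set[str]] = field(default_factory=dict)

    def add(self, mention: ConceptMention) -> None:
        self.left.setdefault(_normalize(mention.left_context), set()).add(mention.patient_id)
        self.right.setdefault(_normalize(mention.right_context), set()).add(mention.patient_id)

    def other_patients(self, mention: ConceptMention) -> int:
        """Largest count of *other* patients sharing either context side."""
        try:
            l = self.left[_normalize(mention.left_context)]
            r = self.right[_normalize(mention.right_context)]
        except KeyError as exc:
            raise ValueError(
                f"mention context not present in index (note {mention.note_id}); "
                "the index must be built from the same corpus"
            ) from exc
        pid = {mention.patient_id}
        return max(len(l - pid), len(r - pid))


def build_context_index(mentions: Iterable[ConceptMention]) -> ContextIndex:
    """Index every mention's left and right context by contributing patient."""
    idx = ContextIndex()
    for m in mentions:
        idx.add(m)
    return idx


def flag_boilerplate(
    mentions: Sequence[ConceptMention],
    index: ContextIndex | None = None,
    min_other_patients: int = 1,
) -> list[ConceptMention]:
    """Return mentions with the ``boilerplate`` flag set where contexts are shared.

    A mention is flagged iff at least ``min_other_patients`` patients other
    than its own produced an identical left context or an identical right
    context.  Duplicated contexts within a single patient's own chart never
    trigger the flag.  If ``index`` is omitted it is built from ``mentions``.
    """
    if index is None:
        index = build_context_index(mentions)
    return [
        replace(m, boilerplate=index.other_patients(m) >= min_other_patients)
        for m in mentions
    ]


def drop_boilerplate(mentions: Iterable[ConceptMention]) -> list[ConceptMention]:
    return [m for m in mentions if not m.boilerplate]


class BoilerplateFlagger(TransformerMixin, BaseEstimator):
    """Corpus-level boilerplate flagger with the sklearn fit/transform shape.

    ``fit`` builds the cross-patient context index from the full corpus of
    mentions; ``transform`` returns the same mentions with boilerplate flags
    set.  The threshold ``min_other_patients`` (default 1) is the number of
    distinct other patients that must share a context before it counts as
    template language.
    """

    def __init__(self, min_other_patients: int = 1):
        self.min_other_patients = min_other_patients

    def fit(self, X: Sequence[ConceptMention], y=None) -> "BoilerplateFlagger":
        self.index_ = build_context_index(X)
        self.n_mentions_ = len(X)
        return self

    def transform(self, X: Sequence[ConceptMention]) -> list[ConceptMention]:
        if not hasattr(self, "index_"):
            raise RuntimeError("BoilerplateFlagger is not fitted")
        return flag_boilerplate(X, self.index_, self.min_other_patients)
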