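"""Dictionary tagging of clinical notes.

Notes are split into sentences, each sentence is tokenized into word tokens
(runs of letters, digits and internal apostrophes), and the token stream is
scanned against the concept dictionary.  Phrase patterns tolerate a bounded
number of intervening word tokens between consecutive pattern words, so the
pattern ``loss cognitive ability`` matches the text ``loss of cognitive
ability``.  Every match is emitted as a :class:`ConceptMention` carrying the
character span in the original note and up to 180 characters of context on
each side, which the boilerplate stage compares across patients.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

from .dictionary import ConceptDictionary, TermPattern

CONTEXT_CHARS = 180

#: Abbreviations after which a period does not end a sentence.
ABBREVIATIONS = frozenset(
    "dr mr mrs ms st vs etc eg ie approx appt dept apt no inc jr sr prof".split()
)


@dataclass(frozen=True)
class Note:
    """One clinical note: free text plus minimal encounter metadata."""

    note_id: str
    patient_id: str
    department: str
    service_date: date
    text: str


@dataclass(frozen=True)
class Token:
    surface: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("token span must be non-empty")

    @property
    def lower(self) -> str:
        return self.surface.lower()


@dataclass(frozen=True)
class ConceptMention:
    """A matched dictionary span in one note."""

    cui: str
    note_id: str
    patient_id: str
    start: int
    end: int
    matched_text: str
    left_context: str
    right_context: str
    boilerplate: bool = False


_SENT_BOUNDARY = re.compile(r"[.!?]+(?=\s+[A-Z0-9])|\n\s*\n")
_TOKEN = re.compile(r"[A-Za-z0-9]+(?:'[A-Za-z0-9]+)*")
_LAST_WORD = re.compile(r"([A-Za-z]+)\.?$")


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Return ordered, non-overlapping ``(start, end)`` sentence spans.

    A sentence ends at terminal punctuation (``. ! ?``) followed by
    whitespace and a capital letter or digit — unless the word before the
    period is a known abbreviation — or at a blank line.  Spans are trimmed
    of surrounding whitespace; the text between consecutive spans is
    delimiter-only, so joining the slices with those delimiters reconstructs
    the input exactly.
    """
    if not text.strip():
        return []
    cut_points: list[int] = []
    for m in _SENT_BOUNDARY.finditer(text):
        if m.group().startswith(("\n",)):
            cut_points.append(m.end())
            continue
        prior = _LAST_WORD.search(text[: m.start() + 1].rstrip("."))
        if prior and prior.group(1).lower() in ABBREVIATIONS:
            continue
        cut_points.append(m.end())
    spans: list[tuple[int, int]] = []
    prev = 0
    for cut in cut_points + [len(text)]:
        seg = text[prev:cut]
        lead = len(seg) - len(seg.lstrip())
        trail = len(seg) - len(seg.rstrip())
        if seg.strip():
            spans.append((prev + lead, cut - trail))
        prev = cut
    return spans


def tokenize(text: str, span: tuple[int, int] | None = None) -> list[Token]:
    """Tokenize ``text`` (or one sentence span of it) into word tokens.

    Tokens are maximal runs of letters/digits with internal apostrophes
    (``can't`` is one token); punctuation is discarded.  Offsets always index
    the full original string.
    """
    lo, hi = span if span is not None else (0, len(text))
    return [
        Token(m.group(), lo + m.start(), lo + m.end())
        for m in _TOKEN.finditer(text[lo:hi])
    ]


def _token_matches(tok: Token, word: str, case_sensitive: bool) -> bool:
    return tok.surface == word if case_sensitive else tok.lower == word


def _min_end(tokens: Sequence[Token], words: tuple[str, ...], max_gap: int,
             case_sensitive: bool, wi: int, prev: int) -> int | None:
    """Smallest final-token index completing ``words[wi:]`` after token ``prev``."""
    if wi == len(words):
        return prev
    best: int | None = None
    for j in range(prev + 1, min(prev + 2 + max_gap, len(tokens) + 1)):
        if j >= len(tokens):
            break
        if _token_matches(tokens[j], words[wi], case_sensitive):
            sub = _min_end(tokens, words, max_gap, case_sensitive, wi + 1, j)
            if sub is not None and (best is None or sub < best):
                best = sub
    return best


def match_pattern(tokens: Sequence[Token], pattern: TermPattern) -> list[tuple[int, int]]:
    """Find pattern matches in one sentence's token list.

    A match is an increasing token subsequence whose surfaces equal the
    pattern words with at most ``max_gap`` intervening tokens between each
    consecutive pair.  Matches are selected leftmost-starting then shortest,
    are non-overlapping, and scanning resumes after each match.  Returns
    ``(first_token_index, last_token_index)`` pairs.
    """
    words = pattern.key_words()
    out: list[tuple[int, int]] = []
    i = 0
    while i < len(tokens):
        if _token_matches(tokens[i], words[0], pattern.case_sensitive):
            end = _min_end(tokens, words, pattern.max_gap, pattern.case_sensitive, 1, i)
            if end is not None:
                out.append((i, end))
                i = end + 1
                continue
        i += 1
    return out


def extract_mentions(note: Note, dictionary: ConceptDictionary) -> list[ConceptMention]:
    """Scan one note against every dictionary pattern.

    The same text span may yield mentions for multiple CUIs (ambiguity is
    preserved); within one CUI, identical spans reached through different
    pattern variants are emitted once.  Output is ordered by ``(start, cui)``.
    """
    text = note.text
    found: set[tuple[str, int, int]] = set()
    # pattern lookup keyed by first word form keeps scanning linear-ish
    by_first: dict[str, list[tuple[str, TermPattern]]] = {}
    cs_patterns: list[tuple[str, TermPattern]] = []
    for entry in dictionary:
        for pat in entry.expanded_patterns():
            if pat.case_sensitive:
                cs_patterns.append((entry.cui, pat))
            else:
                by_first.setdefault(pat.key_words()[0], []).append((entry.cui, pat))
    for span in split_sentences(text):
        tokens = tokenize(text, span)
        first_words = {t.lower for t in tokens}
        candidates = [
            cp for w in first_words for cp in by_first.get(w, ())
        ] + cs_patterns
        for cui, pat in candidates:
            for ti, tj in match_pattern(tokens, pat):
                found.add((cui, tokens[ti].start, tokens[tj].end))
    mentions = [
        ConceptMention(
            cui=cui,
            note_id=note.note_id,
            patient_id=note.patient_id,
            start=s,
            end=e,
            matched_text=text[s:e],
            left_context=text[max(0, s - CONTEXT_CHARS) : s],
            right_context=text[e : e + CONTEXT_CHARS],
        )
        for cui, s, e in found
    ]
    mentions.sort(key=lambda m: (m.start, m.cui, m.end))
    return mentions


def extract_corpus_mentions(
    notes: Iterable[Note], dictionary: ConceptDictionary
) -> list[ConceptMention]:
    """:func:`extract_mentions` over a whole corpus, in note order."""
    out: list[ConceptMention] = []
    for note in notes:
        out.extend(extract_mentions(note, dictionary))
    return out


# ---------------------------------------------------------------------------
# Note / mention I/O: newline-delimited JSON records for notes, flat CSV for
# mentions.
# ---------------------------------------------------------------------------

def write_notes_ndjson(notes: Iterable[Note], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for n in notes:
            fh.write(
                json.dumps(
                    {
                        "note_id": n.note_id,
                        "patient_id": n.patient_id,
                        "department": n.department,
                        "service_date": n.service_date.isoformat(),
                        "text": n.text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_notes_ndjson(path: str | Path) -> list[Note]:
    notes = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            notes.append(
                Note(
                    note_id=str(rec["note_id"]),
                    patient_id=str(rec["patient_id"]),
                    department=rec["department"],
                    service_date=date.fromisoformat(rec["service_date"]),
                    text=rec["text"],
                )
            )
    return notes


_MENTION_FIELDS = [
    "patient_id", "note_id", "cui", "start", "end",
    "matched_text", "left_context", "right_context", "boilerplate",
]


def write_mentions_csv(mentions: Iterable[ConceptMention], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_MENTION_FIELDS)
        for m in mentions:
            w.writerow(
                [m.patient_id, m.note_id, m.cui, m.start, m.end,
                 m.matched_text, m.left_context, m.right_context, int(m.boilerplate)]
            )


def read_mentions_csv(path: str | Path) -> list[ConceptMention]:
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        for rec in csv.DictReader(fh):
            out.append(
                ConceptMention(
                    cui=rec["cui"],
                    note_id=rec["note_id"],
                    patient_id=rec["patient_id"],
                    start=int(rec["start"]),
                    end=int(rec["end"]),
                    matched_text=rec["matched_text"],
                    left_context=rec["left_context"],
                    right_context=rec["right_context"],
                    boilerplate=bool(int(rec["boilerplate"])),
                )
            )
    return out
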