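"""Concept dictionary: terms and phrases mapped to cognitive-impairment CUIs.

The dictionary maps surface terms and multi-word phrases found in clinical
notes to concept unique identifiers (CUIs) — semantic groups such as WANDER
(wandering / getting lost) or DECLINE (declining memory or cognitive
ability).  Each entry carries a role that downstream stages interpret:
``feature`` entries become model predictors, ``patient_exclusion`` entries
(references to stroke, traumatic brain injury, ...) mark patients for removal
from the analytic cohort.

The bundled 42-concept dictionary is a reconstruction from published concept
descriptions, not a verbatim copy of any deployed term list; it is versioned
``table1-reconstruction-1.0`` and every pattern is editable in a flat
line-oriented text file (see :func:`load_dictionary`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

ROLES = frozenset(
    {"feature", "patient_exclusion", "mention_exclusion", "negation_guard"}
)

_VOWELS = set("aeiou")


class DictionaryError(ValueError):
    """Raised for malformed dictionary files or invalid entries."""


@dataclass(frozen=True)
class TermPattern:
    """An ordered word sequence matched with a bounded intervening-word gap.

    ``max_gap`` is the number of extra word tokens permitted between each
    consecutive pair of pattern words; single-word patterns ignore it.
    """

    words: tuple[str, ...]
    max_gap: int = 2
    case_sensitive: bool = False

    def __post_init__(self) -> None:
        if len(self.words) < 1:
            raise DictionaryError("TermPattern needs at least one word")
        if any((not w) or any(c.isspace() for c in w) for w in self.words):
            raise DictionaryError(f"pattern words must be non-empty and whitespace-free: {self.words!r}")
        if self.max_gap < 0:
            raise DictionaryError("max_gap must be non-negative")

    @classmethod
    def from_phrase(cls, phrase: str, max_gap: int = 2, case_sensitive: bool = False) -> "TermPattern":
        return cls(tuple(phrase.split()), max_gap=max_gap, case_sensitive=case_sensitive)

    @property
    def phrase(self) -> str:
        return " ".join(self.words)

    def key_words(self) -> tuple[str, ...]:
        """Word forms as compared during matching (lowercased unless case-sensitive)."""
        if self.case_sensitive:
            return self.words
        return tuple(w.lower() for w in self.words)


def expand_variants(base_word: str) -> set[str]:
    """Return ``base_word`` plus rule-generated English inflections.

    Adds -s / -ed / -ing forms with the usual orthographic adjustments
    (e-drop, consonant+y -> -ies/-ied, final-consonant doubling after a
    single vowel).  The output is always a superset of ``{base_word}`` and
    the rules are purely orthographic — some generated forms are not real
    words, which is harmless because they only widen the match table.
    """
    if not base_word or any(c.isspace() for c in base_word):
        raise DictionaryError(f"invalid base word: {base_word!r}")
    w = base_word
    out = {w}
    if len(w) < 2 or not w.isalpha():
        return out
    last, prev = w[-1], w[-2]

    # plural / third-person -s
    if last in "szx" or w.endswith(("ch", "sh")):
        out.add(w + "es")
    elif last == "y" and prev not in _VOWELS:
        out.add(w[:-1] + "ies")
    else:
        out.add(w + "s")

    doubles = (
        len(w) >= 3
        and last not in _VOWELS
        and last not in "wxy"
        and prev in _VOWELS
        and w[-3] not in _VOWELS
    )

    # past -ed
    if last == "e":
        out.add(w + "d")
    elif last == "y" and prev not in _VOWELS:
        out.add(w[:-1] + "ied")
    else:
        out.add(w + "ed")
        if doubles:
            out.add(w + last + "ed")

    # progressive -ing
    if last == "e" and not w.endswith("ee"):
        out.add(w[:-1] + "ing")
    else:
        out.add(w + "ing")
        if doubles:
            out.add(w + last + "ing")
    return out


@dataclass
class ConceptEntry:
    """One CUI with its surface patterns and downstream role."""

    cui: str
    description: str = ""
    role: str = "feature"
    patterns: list[TermPattern] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.cui or self.cui != self.cui.strip():
            raise DictionaryError(f"invalid CUI: {self.cui!r}")
        if self.role not in ROLES:
            raise DictionaryError(
                f"unknown role {self.role!r} for CUI {self.cui}; expected one of {sorted(ROLES)}"
            )

    def expanded_patterns(self) -> list[TermPattern]:
        """Match-time pattern set: single-word patterns gain inflected variants.

        Multi-word phrases are matched as written — the intervening-word gap
        already gives them flexibility, and expanding every word of a phrase
        would multiply patterns combinatorially for little benefit.
        """
        out: list[TermPattern] = []
        seen: set[tuple[tuple[str, ...], int, bool]] = set()
        for p in self.patterns:
            if len(p.words) == 1:
                variants: Iterable[str] = sorted(expand_variants(p.words[0]))
                cands = [replace(p, words=(v,)) for v in variants]
            else:
                cands = [p]
            for c in cands:
                k = (c.key_words(), c.max_gap, c.case_sensitive)
                if k not in seen:
                    seen.add(k)
                    out.append(c)
        return out


@dataclass
class ConceptDictionary:
    """An ordered collection of concept entries, one per CUI."""

    entries: list[ConceptEntry] = field(default_factory=list)
    version: str = "unversioned"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.cui in seen:
                raise DictionaryError(f"duplicate CUI: {e.cui}")
            seen.add(e.cui)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[ConceptEntry]:
        return iter(self.entries)

    def __getitem__(self, cui: str) -> ConceptEntry:
        for e in self.entries:
            if e.cui == cui:
                return e
        raise KeyError(cui)

    def __contains__(self, cui: str) -> bool:
        return any(e.cui == cui for e in self.entries)

    @property
    def cuis(self) -> list[str]:
        return [e.cui for e in self.entries]

    def feature_cuis(self) -> list[str]:
        return [e.cui for e in self.entries if e.role == "feature"]

    def patient_exclusion_cuis(self) -> list[str]:
        return [e.cui for e in self.entries if e.role == "patient_exclusion"]


# ---------------------------------------------------------------------------
# File format: flat, line-oriented, tab-separated.
#
#   #mciscreen-dictionary
#   #version: <label>
#   #fields: cui  role  max_gap  description  patterns
#   WANDER<TAB>feature<TAB>2<TAB>Wandering or getting lost<TAB>wander|getting lost
#
# Patterns are separated by "|"; phrase words by single spaces.  An empty
# patterns field is legal (a concept may be defined but have no active terms).
# ---------------------------------------------------------------------------

_MAGIC = "#mciscreen-dictionary"


def load_dictionary(path: str | Path) -> ConceptDictionary:
    """Load a concept dictionary from its flat text format.

    Raises :class:`DictionaryError` on duplicate CUIs, unknown roles, or an
    empty file.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    version = "unversioned"
    entries: list[ConceptEntry] = []
    seen: set[str] = set()
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            if line.startswith("#version:"):
                version = line.split(":", 1)[1].strip()
            continue
        parts = line.split("\t")
        if len(parts) != 5:
            raise DictionaryError(f"{path}:{lineno}: expected 5 tab-separated fields, got {len(parts)}")
        cui, role, max_gap_s, description, patterns_s = parts
        cui = cui.strip()
        if cui in seen:
            raise DictionaryError(f"{path}:{lineno}: duplicate CUI: {cui}")
        seen.add(cui)
        try:
            max_gap = int(max_gap_s)
        except ValueError as exc:
            raise DictionaryError(f"{path}:{lineno}: bad max_gap {max_gap_s!r}") from exc
        patterns = [
            TermPattern.from_phrase(ph, max_gap=max_gap)
            for ph in patterns_s.split("|")
            if ph.strip()
        ]
        entries.append(ConceptEntry(cui=cui, description=description, role=role.strip(), patterns=patterns))
    if not entries:
        raise DictionaryError(f"{path}: empty dictionary file")
    d = ConceptDictionary(entries=entries, version=version)
    logger.info("loaded dictionary %s: %d CUIs from %s", version, len(d), path)
    return d


def save_dictionary(d: ConceptDictionary, path: str | Path) -> None:
    """Write ``d`` in the flat text format (inverse of :func:`load_dictionary`)."""
    path = Path(path)
    lines = [_MAGIC, f"#version: {d.version}", "#fields: cui\trole\tmax_gap\tdescription\tpatterns"]
    for e in d.entries:
        max_gap = e.patterns[0].max_gap if e.patterns else 2
        pats = "|".join(p.phrase for p in e.patterns)
        lines.append(f"{e.cui}\t{e.role}\t{max_gap}\t{e.description}\t{pats}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass
class ValidationReport:
    """Read-only audit of a dictionary: suspicious but not fatal findings."""

    n_cuis: int
    zero_pattern_cuis: list[str]
    ambiguous_phrases: dict[str, list[str]]  # phrase -> CUIs sharing it
    roles: dict[str, list[str]]  # role -> CUIs

    @property
    def ok(self) -> bool:
        return not self.zero_pattern_cuis and not self.ambiguous_phrases


def validate_dictionary(d: ConceptDictionary) -> ValidationReport:
    """Report zero-pattern CUIs, phrases shared between CUIs, and role assignments."""
    zero = [e.cui for e in d.entries if not e.patterns]
    by_phrase: dict[str, list[str]] = {}
    for e in d.entries:
        for p in e.patterns:
            by_phrase.setdefault(" ".join(p.key_words()), []).append(e.cui)
    ambiguous = {ph: cuis for ph, cuis in by_phrase.items() if len(set(cuis)) > 1}
    roles: dict[str, list[str]] = {}
    for e in d.entries:
        roles.setdefault(e.role, []).append(e.cui)
    return ValidationReport(
        n_cuis=len(d), zero_pattern_cuis=zero, ambiguous_phrases=ambiguous, roles=roles
    )


def bundled_dictionary_path(name: str = "mci") -> Path:
    """Path to a dictionary shipped with the package: ``mci`` (42 CUIs) or ``toy``."""
    fname = {"mci": "mci_dictionary.tsv", "toy": "toy_dictionary.tsv"}[name]
    return Path(str(resources.files("mciscreen.data").joinpath(fname)))


def load_bundled_dictionary(name: str = "mci") -> ConceptDictionary:
    return load_dictionary(bundled_dictionary_path(name))
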