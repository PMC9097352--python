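from datetime import date

import numpy as np
import pytest

from mciscreen.dictionary import ConceptDictionary, ConceptEntry, TermPattern
from mciscreen.text_matcher import (
    Note, extract_mentions, match_pattern, read_notes_ndjson, split_sentences,
    tokenize, write_notes_ndjson,
)

from .oracles import brute_force_matches, random_toy_setup


class TestSplitSentences:
    @pytest.mark.parametrize(
        "text,n",
        [
            ("Pt forgets names. Daughter concerned.", 2),
            ("", 0),
            ("   \n ", 0),
            ("Dr. Smith called.", 1),  # abbreviation does not split
            ("One sentence only", 1),
            ("First line.\n\nSecond paragraph without caps", 2),
            ("Really? Yes. Fine!", 3),
        ],
    )
    def test_span_counts(self, text, n):
        assert len(split_sentences(text)) == n

    def test_spans_reconstruct_input(self):
        text = "Pt stable.  Daughter concerned. Follow up in 3 months."
        spans = split_sentences(text)
        assert [s for s, _ in spans] == sorted(s for s, _ in spans)
        rebuilt = []
        prev = 0
        for s, e in spans:
            assert text[prev:s].strip() == ""  # only delimiters between spans
            rebuilt.append(text[s:e])
            prev = e
        assert "".join(rebuilt).replace(" ", "") in text.replace(" ", "")

    def test_spans_cover_all_nonspace_text(self):
        text = "A note. Another note!\n\nLast bit"
        covered = set()
        for s, e in split_sentences(text):
            covered.update(range(s, e))
        for i, ch in enumerate(text):
            if not ch.isspace():
                assert i in covered


class TestTokenize:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("loss of cognitive ability", ["loss", "of", "cognitive", "ability"]),
            ("can't remember", ["can't", "remember"]),
            ("MMSE=24.", ["MMSE", "24"]),
            ("", []),
            ("...", []),
            ("a-b c_d", ["a", "b", "c", "d"]),
        ],
    )
    def test_surfaces(self, text, expected):
        assert [t.surface for t in tokenize(text)] == expected

    def test_offsets_index_original_note(self):
        text = "Header here. MMSE=24 noted."
        span = split_sentences(text)[1]
        for t in tokenize(text, span):
            assert text[t.start : t.end] == t.surface

    def test_tokens_ordered_nonoverlapping(self):
        toks = tokenize("one two three four")
        for a, b in zip(toks, toks[1:]):
            assert a.end <= b.start


class TestMatchPattern:
    def test_gap_tolerant_phrase_match(self):
        toks = tokenize("loss of cognitive ability")
        p = TermPattern.from_phrase("loss cognitive ability")
        assert match_pattern(toks, p) == [(0, 3)]

    def test_three_intervening_words_is_too_many(self):
        toks = tokenize("loss of the precious cognitive ability")
        p = TermPattern.from_phrase("loss cognitive ability")
        assert match_pattern(toks, p) == []

    def test_single_word_repeated(self):
        toks = tokenize("forget to forget")
        assert match_pattern(toks, TermPattern.from_phrase("forget")) == [(0, 0), (2, 2)]

    def test_zero_gap_requires_adjacency(self):
        toks = tokenize("memory rapid decline")
        p = TermPattern(("memory", "decline"), max_gap=0)
        assert match_pattern(toks, p) == []
        assert match_pattern(tokenize("memory decline"), p) == [(0, 1)]

    def test_backtracking_finds_later_completion(self):
        # greedy earliest-next would bind the first "b" and miss the match:
        # "c" is reachable only through the second "b"
        toks = tokenize("a b x b x x c")
        p = TermPattern(("a", "b", "c"), max_gap=2)
        assert match_pattern(toks, p) == [(0, 6)]

    def test_leftmost_then_shortest_nonoverlapping(self):
        toks = tokenize("a b a b")
        p = TermPattern(("a", "b"), max_gap=2)
        assert match_pattern(toks, p) == [(0, 1), (2, 3)]

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sentences, patterns = random_toy_setup(rng)
        for sent in sentences:
            toks = tokenize(" ".join(sent))
            for words, gap in patterns:
                got = match_pattern(toks, TermPattern(words, max_gap=gap))
                want = brute_force_matches([t.surface for t in toks], words, gap)
                assert got == want, (sent, words, gap)


def _toy(entries):
    return ConceptDictionary(
        entries=[ConceptEntry(cui, patterns=[TermPattern.from_phrase(p) for p in pats])
                 for cui, pats in entries],
        version="test",
    )


class TestExtractMentions:
    def test_single_word_mention_with_variant(self, note_factory, toy_dict):
        note = note_factory("Patient wanders at night.")
        ms = extract_mentions(note, toy_dict)
        assert [(m.cui, m.matched_text) for m in ms] == [("WANDER", "wanders")]

    def test_phrase_mention_contexts(self, note_factory, toy_dict):
        pad = "x" * 200
        note = note_factory(f"{pad} loss of cognitive ability {pad}")
        (m,) = extract_mentions(note, toy_dict)
        assert m.cui == "DECLINE"
        assert note.text[m.start : m.end] == m.matched_text == "loss of cognitive ability"
        assert len(m.left_context) == 180 and len(m.right_context) == 180
        assert note.text[m.start - 180 : m.start] == m.left_context

    def test_short_note_truncates_context(self, note_factory, toy_dict):
        note = note_factory("Tends to wander often.")
        (m,) = extract_mentions(note, toy_dict)
        assert m.left_context == "Tends to "
        assert len(m.left_context) < 180

    def test_empty_note(self, note_factory, toy_dict):
        assert extract_mentions(note_factory(""), toy_dict) == []

    def test_matches_never_cross_sentences(self, note_factory):
        d = _toy([("X", ["memory decline"])])
        note = note_factory("Has good memory. Decline was discussed.")
        assert extract_mentions(note, d) == []

    def test_ambiguity_across_cuis_preserved(self, note_factory):
        d = _toy([("A", ["memory decline"]), ("B", ["memory decline"])])
        note = note_factory("Noted memory decline today.")
        assert [m.cui for m in extract_mentions(note, d)] == ["A", "B"]

    def test_deterministic_ordering(self, note_factory, toy_dict):
        note = note_factory("Tends to wander and forget names; memory decline evident.")
        ms1 = extract_mentions(note, toy_dict)
        ms2 = extract_mentions(note, toy_dict)
        assert ms1 == ms2
        assert [(m.start, m.cui) for m in ms1] == sorted((m.start, m.cui) for m in ms1)

    @pytest.mark.parametrize("seed", range(10))
    def test_corpus_equals_oracle_per_sentence(self, seed, note_factory):
        # end-to-end extraction agrees with brute-force matching applied
        # sentence by sentence over a random corpus
        rng = np.random.default_rng(1000 + seed)
        sentences, patterns = random_toy_setup(rng)
        d = ConceptDictionary(
            entries=[
                ConceptEntry(f"C{i}", patterns=[TermPattern(w, max_gap=g)])
                for i, (w, g) in enumerate(patterns)
            ]
        )
        text = ". ".join(" ".join(s).capitalize() for s in sentences) + "."
        note = note_factory(text)
        got = {(m.cui, m.start, m.end) for m in extract_mentions(note, d)}
        want = set()
        for span in split_sentences(text):
            toks = tokenize(text, span)
            for i, (words, gap) in enumerate(patterns):
                for a, b in brute_force_matches([t.surface for t in toks], words, gap):
                    want.add((f"C{i}", toks[a].start, toks[b].end))
        assert got == want

    def test_offset_fidelity_on_full_dictionary(self, note_factory, full_dict):
        note = note_factory(
            "Daughter called about memory problems. Patient often wanders and "
            "forgets appointments; donepezil was discussed. Dr. Notes indicate "
            "loss of some cognitive ability."
        )
        ms = extract_mentions(note, full_dict)
        assert ms, "expected mentions in a phrase-dense note"
        for m in ms:
            assert note.text[m.start : m.end] == m.matched_text


def test_notes_ndjson_round_trip(tmp_path, note_factory):
    notes = [
        note_factory("Text with \"quotes\" and\nnewlines.", note_id="a"),
        Note("b", "p2", "BehavioralHealth", date(2011, 2, 3), ""),
    ]
    path = tmp_path / "notes.ndjson"
    write_notes_ndjson(notes, path)
    assert read_notes_ndjson(path) == notes
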