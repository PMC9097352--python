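"""Synthetic clinical corpus with known ground truth.

Real clinical free text cannot be shared, so every stage of the pipeline is
exercised on generated data whose statistical structure mirrors the study
population: multi-note patients over a 2-year lookback, notes of a few
hundred words, dictionary phrases planted at rates that depend on a latent
MCI state, shared boilerplate template blocks, demographics drawn from the
published cohort strata, and instrument scores whose <= 26 positivity
follows the latent state up to a configurable measurement-noise rate.

Every planted phrase is recorded with its exact character span, so
extraction recall, boilerplate flagging and end-to-end model performance can
all be checked against construction-time truth.

Design notes
------------
* Each note opens and closes with a sentence containing its unique note id.
  Context windows that are not fully inside a shared template block
  therefore never coincide across patients, which makes boilerplate
  flagging exactly predictable.
* Template blocks carry at least 180 characters of fixed template text on
  both sides of any embedded phrase, so both context windows of a template
  mention lie inside the block and are shared verbatim by every patient who
  received the template.
* The filler vocabulary is filtered against every dictionary pattern word,
  so generated filler can never complete a dictionary pattern: the only
  mentions in the corpus are the planted ones (plus sub-phrase matches of
  other concepts inside planted phrases, which are themselves recorded
  behaviours of the matcher, not generator accidents).
* All randomness flows from one root seed through named substreams
  (patients, notes, scores), so regenerating any part is stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CodedEvent, InstrumentScore, PatientRecord
from .dictionary import ConceptDictionary
from .text_matcher import Note

# Age bands and demographic strata default to the published general-population
# cohort composition.
DEFAULT_AGE_BANDS: dict[tuple[int, int], float] = {
    (65, 69): 0.1907,
    (70, 74): 0.2154,
    (75, 79): 0.1928,
    (80, 84): 0.1882,
    (85, 94): 0.2129,
}
DEFAULT_SEX = {"F": 0.5935, "M": 0.4065}
DEFAULT_RACE = {
    "White": 0.8984,
    "Asian": 0.0435,
    "Black": 0.0213,
    "AmericanIndian": 0.0109,
    "PacificIslander": 0.0004,
    "Other": 0.0063,
    "Unknown": 0.0192,
}
DEFAULT_ETHNICITY = {"NotHispanic": 0.9406, "Hispanic": 0.0393, "Unknown": 0.0201}

_BASE_FILLER = (
    "followup routine stable reviewed labs ordered diet exercise sleep "
    "appetite gait steady lungs clear regular rhythm abdomen soft benign "
    "skin warm alert oriented ambulating independently tolerating current "
    "regimen continue clinic weeks blood pressure controlled knee chronic "
    "improving discussed options questions answered return sooner needed "
    "vaccination reviewed screening current immunizations updated hydration "
    "encouraged activity moderate walking daily stretches posture balance "
    "footwear supportive vision checked hearing adequate dental cleaning "
    "scheduled nutrition fiber vegetables portions smaller evening earlier "
    "bedtime consistent caffeine reduced afternoon energy improved mood "
    "pleasant cooperative engaged conversational vitals recorded temperature "
    "afebrile pulse oximetry saturation adequate respirations unlabored"
).split()

_SIGNAL_CUIS = (
    "DECLINE", "FORGET", "FORGETFL", "WANDER", "CONCERN",
    "CALLED", "WITHX", "DONEPEZIL", "DEMENTIA", "CONCENTR",
)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    Defaults emulate the published general-population cohort: 2391 patients,
    ~10 notes per patient in the 730-day lookback, ~260 words per note, the
    published age/sex/race strata, an MCI prevalence near 31% with the
    published age and sex gradients, and a 10% chance that the instrument
    label disagrees with the latent state (imperfect MMSE/MoCA measurement).
    """

    n_patients: int = 2391
    seed: int = 0
    age_band_weights: Mapping[tuple[int, int], float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_BANDS))
    sex_weights: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SEX))
    race_weights: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_RACE))
    ethnicity_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ETHNICITY))
    low_income_rate: float = 0.0088
    low_education_rate: float = 0.3352
    neighborhood_missing_rate: float = 0.0079
    notes_per_patient_mean: float = 9.0  # Poisson mean; +1 so every patient has notes
    words_per_note_mean: float = 260.0
    words_per_note_sd: float = 120.0
    words_per_note_min: int = 30
    department_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "FamilyPractice": 0.80, "BehavioralHealth": 0.14,
            "Neurology": 0.05, "SpeechLanguagePathology": 0.01,
        })
    # latent MCI model: logit(p) = b0 + b_age*(age-75) + b_female*1[F]
    latent_intercept: float = -0.95
    latent_age_coef: float = 0.0626
    latent_female_coef: float = 0.18
    # per-note phrase plant probability by CUI: (rate | latent-, rate | latent+)
    mention_rates: Mapping[str, tuple[float, float]] | None = None
    boilerplate_rate: float = 0.25
    n_boilerplate_templates: int = 12
    gap_insert_rate: float = 0.25
    score_noise: float = 0.10
    act_participant_rate: float = 0.0
    exclusion_code_rates: Mapping[str, float] = field(default_factory=dict)
    index_date_range: tuple[date, date] = (date(2006, 1, 1), date(2015, 9, 30))

    def validate(self) -> None:
        for name, v in (
            ("low_income_rate", self.low_income_rate),
            ("low_education_rate", self.low_education_rate),
            ("neighborhood_missing_rate", self.neighborhood_missing_rate),
            ("boilerplate_rate", self.boilerplate_rate),
            ("gap_insert_rate", self.gap_insert_rate),
            ("score_noise", self.score_noise),
            ("act_participant_rate", self.act_participant_rate),
        ):
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mention_rates is not None:
            for cui, (r0, r1) in self.mention_rates.items():
                if not (0 <= r0 <= 1 and 0 <= r1 <= 1):
                    raise ValueError(f"mention rate for {cui} outside [0, 1]")
        for wname, w in (
            ("age_band_weights", self.age_band_weights),
            ("sex_weights", self.sex_weights),
            ("race_weights", self.race_weights),
            ("ethnicity_weights", self.ethnicity_weights),
            ("department_weights", self.department_weights),
        ):
            total = sum(w.values())
            if total <= 0 or any(v < 0 for v in w.values()):
                raise ValueError(f"{wname} must be non-negative with positive sum")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")

    # -- presets used by the end-to-end checks ------------------------------

    @classmethod
    def strong_signal(cls, n_patients: int = 2000, seed: int = 0) -> "GeneratorConfig":
        """Large status-dependent phrase-rate separation, near-noiseless labels.

        Label noise bounds attainable discrimination at roughly 1 - noise, so
        a deliberately strong-signal condition uses a 2% disagreement rate.
        Note sizes are scaled down (5-ish notes of ~120 words) to keep
        end-to-end runs cheap; signal strength does not depend on them.
        """
        rates = {c: (0.01, 0.45) for c in _SIGNAL_CUIS}
        return cls(
            n_patients=n_patients, seed=seed, mention_rates=rates,
            notes_per_patient_mean=4.0, words_per_note_mean=120.0,
            words_per_note_sd=40.0, score_noise=0.02,
        )

    @classmethod
    def null_signal(cls, n_patients: int = 2000, seed: int = 0) -> "GeneratorConfig":
        """No association between notes, demographics and the label."""
        rates = {c: (0.05, 0.05) for c in _SIGNAL_CUIS}
        return cls(
            n_patients=n_patients, seed=seed, mention_rates=rates,
            notes_per_patient_mean=4.0, words_per_note_mean=120.0,
            words_per_note_sd=40.0,
            latent_intercept=-0.8, latent_age_coef=0.0, latent_female_coef=0.0,
        )


def default_mention_rates(
    dictionary: ConceptDictionary, negative_rate: float = 0.01, positive_rate: float = 0.08
) -> dict[str, tuple[float, float]]:
    """Status-dependent rates for known signal concepts, flat elsewhere."""
    rates: dict[str, tuple[float, float]] = {}
    for cui in dictionary.feature_cuis():
        if cui in _SIGNAL_CUIS:
            rates[cui] = (negative_rate, positive_rate)
        else:
            rates[cui] = (0.005, 0.005)
    return rates


@dataclass
class SyntheticCohort:
    patients: list[PatientRecord]
    index_dates: dict[str, date]
    notes: list[Note]
    latent: dict[str, int]
    labels: dict[str, int]
    ground_truth: pd.DataFrame  # one row per planted mention
    config: GeneratorConfig


def _filler_vocab(dictionary: ConceptDictionary) -> list[str]:
    banned: set[str] = set()
    for entry in dictionary:
        for pat in entry.expanded_patterns():
            banned.update(pat.key_words())
    vocab = [w for w in _BASE_FILLER if w.lower() not in banned]
    if len(vocab) < 20:
        raise ValueError("filler vocabulary too small after removing dictionary words")
    return vocab


def _weighted_choice(rng: np.random.Generator, weights: Mapping, size=None):
    keys = list(weights.keys())
    w = np.array([weights[k] for k in keys], dtype=float)
    w = w / w.sum()
    idx = rng.choice(len(keys), size=size, p=w)
    if size is None:
        return keys[int(idx)]
    return [keys[int(i)] for i in idx]


def _filler_sentence(rng: np.random.Generator, vocab: list[str], n_words: int) -> str:
    words = [vocab[int(i)] for i in rng.integers(len(vocab), size=n_words)]
    return words[0].capitalize() + " " + " ".join(words[1:]) + "."


@dataclass(frozen=True)
class _Template:
    """A fixed boilerplate block; ``phrase_offset`` spans the embedded phrase."""

    text: str
    cui: str | None
    phrase_start: int  # offsets into text; -1 when no phrase embedded
    phrase_end: int


def _build_templates(
    dictionary: ConceptDictionary, vocab: list[str], n_templates: int,
    rng: np.random.Generator,
) -> list[_Template]:
    """Fixed text blocks with >= 180 chars of template text around any phrase."""
    templates: list[_Template] = []
    phrased = [e for e in dictionary if e.patterns and e.role == "feature"]
    for t in range(n_templates):
        pre = " ".join(
            _filler_sentence(rng, vocab, int(rng.integers(8, 13))) for _ in range(5)
        )
        post = " ".join(
            _filler_sentence(rng, vocab, int(rng.integers(8, 13))) for _ in range(5)
        )
        assert len(pre) >= 180 and len(post) >= 180
        if phrased and t % 2 == 0:
            entry = phrased[int(rng.integers(len(phrased)))]
            pat = entry.patterns[int(rng.integers(len(entry.patterns)))]
            phrase = " ".join(pat.words)
            mid = "Template reminder, " + phrase + " as instructed."
            start = len(pre) + 1 + len("Template reminder, ")
            templates.append(
                _Template(
                    text=pre + " " + mid + " " + post,
                    cui=entry.cui,
                    phrase_start=start,
                    phrase_end=start + len(phrase),
                )
            )
        else:
            templates.append(
                _Template(text=pre + " " + post, cui=None, phrase_start=-1, phrase_end=-1)
            )
    return templates


def generate_note(
    latent_status: int,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    dictionary: ConceptDictionary,
    *,
    note_id: str,
    patient_id: str,
    department: str,
    service_date: date,
    vocab: list[str] | None = None,
    templates: Sequence[_Template] = (),
    mention_rates: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[Note, list[dict]]:
    """One note plus ground-truth records for every planted phrase.

    The note opens and closes with sentences containing the note id; planted
    phrases sit in their own sentences, optionally with 1-2 filler words
    inserted inside multi-word phrases (still within the matcher's gap
    tolerance); an optional boilerplate template block is inserted verbatim.
    """
    if vocab is None:
        vocab = _filler_vocab(dictionary)
    if mention_rates is None:
        mention_rates = cfg.mention_rates or default_mention_rates(dictionary)

    pieces: list[tuple[str, list[dict]]] = []  # (sentence text, truth records w/ local offsets)

    for entry in dictionary:
        if not entry.patterns:
            continue
        rates = mention_rates.get(entry.cui)
        if rates is None:
            continue
        rate = rates[1] if latent_status else rates[0]
        if rng.random() >= rate:
            continue
        pat = entry.patterns[int(rng.integers(len(entry.patterns)))]
        words = list(pat.words)
        if len(words) > 1 and pat.max_gap > 0 and rng.random() < cfg.gap_insert_rate:
            gap_at = int(rng.integers(1, len(words)))
            n_ins = int(rng.integers(1, pat.max_gap + 1))
            fillers = [vocab[int(i)] for i in rng.integers(len(vocab), size=n_ins)]
            words = words[:gap_at] + fillers + words[gap_at:]
        phrase = " ".join(words)
        # the note id on both sides of the phrase keeps every non-template
        # context window unique across patients, so boilerplate flagging is
        # exactly predictable from construction
        prefix = f"Per note {note_id} review, "
        sentence = prefix + phrase + f" as documented in {note_id}."
        pieces.append(
            (
                sentence,
                [{
                    "cui": entry.cui,
                    "local_start": len(prefix),
                    "local_end": len(prefix) + len(phrase),
                    "text": phrase,
                    "is_template": False,
                    "template_id": -1,
                }],
            )
        )

    if templates and rng.random() < cfg.boilerplate_rate:
        t_idx = int(rng.integers(len(templates)))
        tpl = templates[t_idx]
        recs = []
        if tpl.cui is not None:
            recs.append(
                {
                    "cui": tpl.cui,
                    "local_start": tpl.phrase_start,
                    "local_end": tpl.phrase_end,
                    "text": tpl.text[tpl.phrase_start : tpl.phrase_end],
                    "is_template": True,
                    "template_id": t_idx,
                }
            )
        pieces.append((tpl.text, recs))

    target_words = max(
        cfg.words_per_note_min,
        int(rng.normal(cfg.words_per_note_mean, cfg.words_per_note_sd)),
    )
    n_words = sum(len(s.split()) for s, _ in pieces)
    while n_words < target_words:
        k = int(rng.integers(6, 15))
        pieces.append((_filler_sentence(rng, vocab, k), []))
        n_words += k

    order = list(rng.permutation(len(pieces)))
    header = f"Encounter {note_id} documented {service_date.isoformat()}."
    footer = f"End of encounter {note_id}."
    text_parts = [header]
    truth: list[dict] = []
    offset = len(header)
    for i in order:
        sentence, recs = pieces[i]
        offset += 1  # joining space
        for r in recs:
            truth.append(
                {
                    "patient_id": patient_id,
                    "note_id": note_id,
                    "cui": r["cui"],
                    "start": offset + r["local_start"],
                    "end": offset + r["local_end"],
                    "text": r["text"],
                    "is_template": r["is_template"],
                    "template_id": r["template_id"],
                }
            )
        text_parts.append(sentence)
        offset += len(sentence)
    text_parts.append(footer)
    text = " ".join(text_parts)
    note = Note(
        note_id=note_id, patient_id=patient_id, department=department,
        service_date=service_date, text=text,
    )
    for r in truth:
        assert text[r["start"] : r["end"]] == r["text"]
    return note, truth


_TRUTH_COLUMNS = [
    "patient_id", "note_id", "cui", "start", "end", "text", "is_template", "template_id",
]


def generate_cohort(
    cfg: GeneratorConfig, dictionary: ConceptDictionary
) -> SyntheticCohort:
    """Generate patients, notes, scores and ground truth under ``cfg``.

    Substreams: patient attributes come from the ``patients`` stream, each
    note from a stream keyed by (seed, patient index, note index), scores
    from the ``scores`` stream, so partial regeneration is stable.
    """
    cfg.validate()
    pat_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    score_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    tpl_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))

    vocab = _filler_vocab(dictionary)
    templates = _build_templates(dictionary, vocab, cfg.n_boilerplate_templates, tpl_rng)
    mention_rates = cfg.mention_rates or default_mention_rates(dictionary)

    lo_idx, hi_idx = cfg.index_date_range
    idx_span = (hi_idx - lo_idx).days

    patients: list[PatientRecord] = []
    index_dates: dict[str, date] = {}
    latent: dict[str, int] = {}
    labels: dict[str, int] = {}
    notes: list[Note] = []
    truth_rows: list[dict] = []

    code_plants = list(cfg.exclusion_code_rates.items())

    for i in range(cfg.n_patients):
        pid = f"P{i:05d}"
        band = _weighted_choice(pat_rng, cfg.age_band_weights)
        age = int(pat_rng.integers(band[0], band[1] + 1))
        sex = _weighted_choice(pat_rng, cfg.sex_weights)
        race = _weighted_choice(pat_rng, cfg.race_weights)
        eth = _weighted_choice(pat_rng, cfg.ethnicity_weights)
        index_date = lo_idx + timedelta(days=int(pat_rng.integers(idx_span + 1)))
        try:
            birth = index_date.replace(year=index_date.year - age)
        except ValueError:  # Feb 29 anchored on a non-leap birth year
            birth = index_date.replace(year=index_date.year - age, day=28)
        birth -= timedelta(days=int(pat_rng.integers(0, 330)))

        if pat_rng.random() < cfg.neighborhood_missing_rate:
            low_inc = low_edu = None
        else:
            low_inc = bool(pat_rng.random() < cfg.low_income_rate)
            low_edu = bool(pat_rng.random() < cfg.low_education_rate)

        eta = (
            cfg.latent_intercept
            + cfg.latent_age_coef * (age - 75)
            + cfg.latent_female_coef * (sex == "F")
        )
        p_mci = 1.0 / (1.0 + np.exp(-eta))
        z = int(pat_rng.random() < p_mci)
        latent[pid] = z
        y = z if score_rng.random() >= cfg.score_noise else 1 - z
        labels[pid] = y
        score_val = (
            int(score_rng.integers(10, 27)) if y else int(score_rng.integers(27, 31))
        )

        codes: list[CodedEvent] = []
        for category_code, rate in code_plants:
            if pat_rng.random() < rate:
                cat, code = category_code.split(":", 1)
                kind = "medication" if cat.endswith("medication") else "diagnosis"
                codes.append(
                    CodedEvent(
                        date=index_date - timedelta(days=int(pat_rng.integers(1, 700))),
                        kind=kind, code=code,
                    )
                )

        enroll = [(index_date - timedelta(days=800), index_date + timedelta(days=60))]
        n_notes = 1 + int(pat_rng.poisson(cfg.notes_per_patient_mean))
        visit_days = sorted(int(d) for d in pat_rng.integers(1, 730, size=n_notes))
        patient_notes: list[Note] = []
        for j, back in enumerate(visit_days):
            nid = f"{pid}-N{j:03d}"
            note_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7, i, j]))
            dept = _weighted_choice(note_rng, cfg.department_weights)
            svc = index_date - timedelta(days=back)
            note, truth = generate_note(
                z, cfg, note_rng, dictionary,
                note_id=nid, patient_id=pid, department=dept, service_date=svc,
                vocab=vocab, templates=templates, mention_rates=mention_rates,
            )
            patient_notes.append(note)
            truth_rows.extend(truth)

        patients.append(
            PatientRecord(
                patient_id=pid, birth_date=birth, sex=sex, race=race, ethnicity=eth,
                enrollment_spans=enroll, structured_codes=codes,
                scores=[InstrumentScore("MMSE", score_val, index_date)],
                visit_dates=[n.service_date for n in patient_notes],
                low_income=low_inc, low_education=low_edu,
                act_participant=bool(pat_rng.random() < cfg.act_participant_rate),
            )
        )
        index_dates[pid] = index_date
        notes.extend(patient_notes)

    ground_truth = pd.DataFrame(truth_rows, columns=_TRUTH_COLUMNS)
    return SyntheticCohort(
        patients=patients, index_dates=index_dates, notes=notes,
        latent=latent, labels=labels, ground_truth=ground_truth, config=cfg,
    )


def mention_key(m) -> tuple:
    """Identity of a mention for truth comparisons (works for rows and mentions)."""
    return (m.patient_id, m.note_id, m.cui, int(m.start), int(m.end))


def expected_boilerplate_keys(ground_truth: pd.DataFrame) -> set[tuple]:
    """Mention keys that cross-patient boilerplate flagging must mark.

    Exactly the template-embedded phrases whose template block appears in
    notes of at least two distinct patients.  Exact for dictionaries whose
    patterns do not nest inside each other (such as the bundled toy
    dictionary); nested patterns can add legitimate extra matches inside a
    template block that the ground-truth table does not enumerate.
    """
    tpl = ground_truth[ground_truth.is_template]
    if tpl.empty:
        return set()
    counts = tpl.groupby("template_id").patient_id.nunique()
    return {
        mention_key(r) for r in tpl.itertuples() if counts[r.template_id] >= 2
    }


# -- tabular export -----------------------------------------------------------

def patients_to_frame(cohort: SyntheticCohort) -> pd.DataFrame:
    """Flatten the patient records (one row per patient) for CSV export."""
    rows = []
    for p in cohort.patients:
        s = p.scores[0]
        rows.append(
            {
                "patient_id": p.patient_id,
                "birth_date": p.birth_date.isoformat(),
                "sex": p.sex,
                "race": p.race,
                "ethnicity": p.ethnicity,
                "index_date": cohort.index_dates[p.patient_id].isoformat(),
                "enrollment_start": p.enrollment_spans[0][0].isoformat(),
                "enrollment_end": p.enrollment_spans[0][1].isoformat(),
                "instrument": s.instrument,
                "score": s.score,
                "score_date": s.date.isoformat(),
                "low_income": "" if p.low_income is None else int(p.low_income),
                "low_education": "" if p.low_education is None else int(p.low_education),
                "act_participant": int(p.act_participant),
                "visit_dates": ";".join(d.isoformat() for d in p.visit_dates),
                "codes": ";".join(f"{e.date.isoformat()}|{e.kind}|{e.code}"
                                  for e in p.structured_codes),
            }
        )
    return pd.DataFrame(rows)


def patients_from_frame(frame: pd.DataFrame) -> tuple[list[PatientRecord], dict[str, date]]:
    patients = []
    index_dates = {}
    for rec in frame.to_dict("records"):
        codes = []
        raw_codes = rec.get("codes", "")
        if isinstance(raw_codes, str) and raw_codes:
            for item in raw_codes.split(";"):
                d, kind, code = item.split("|")
                codes.append(CodedEvent(date.fromisoformat(d), kind, code))
        li = rec.get("low_income", "")
        le = rec.get("low_education", "")
        patients.append(
            PatientRecord(
                patient_id=str(rec["patient_id"]),
                birth_date=date.fromisoformat(rec["birth_date"]),
                sex=rec["sex"], race=rec["race"], ethnicity=rec["ethnicity"],
                enrollment_spans=[(date.fromisoformat(rec["enrollment_start"]),
                                   date.fromisoformat(rec["enrollment_end"]))],
                structured_codes=codes,
                scores=[InstrumentScore(rec["instrument"], int(rec["score"]),
                                        date.fromisoformat(rec["score_date"]))],
                visit_dates=[
                    date.fromisoformat(v)
                    for v in str(rec.get("visit_dates", "") or "").split(";")
                    if v and v != "nan"
                ],
                low_income=None if li in ("", None) or pd.isna(li) else bool(int(li)),
                low_education=None if le in ("", None) or pd.isna(le) else bool(int(le)),
                act_participant=bool(int(rec.get("act_participant", 0))),
            )
        )
        index_dates[str(rec["patient_id"])] = date.fromisoformat(rec["index_date"])
    return patients, index_dates


def generate_planted_design(
    n: int, p: int, n_true: int = 3, effect: float = 0.8,
    intercept: float = -0.5, seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Gaussian design with a sparse true coefficient vector for recovery checks.

    Returns (X, y, beta) where beta has ``n_true`` nonzero entries of
    magnitude ``effect`` with alternating signs and y ~ Bernoulli(sigmoid(
    intercept + X beta)).
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    true_idx = rng.choice(p, size=n_true, replace=False)
    for k, j in enumerate(sorted(true_idx)):
        beta[j] = effect * (1 if k % 2 == 0 else -1)
    eta = intercept + X @ beta
    y = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta)))
    cols = [f"x{j:02d}" for j in range(p)]
    return pd.DataFrame(X, columns=cols), y, beta
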