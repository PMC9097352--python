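"""Cohort construction: index dates, eligibility, matching, note windows, splits.

The analysis anchors every patient at an *index date* — for general-population
cases the first structured MCI diagnosis (here, the date the cognitive
instrument was administered coincides with it), for longitudinal-study
participants the first positive CASI screen (score <= 85).  Matched controls
inherit their case's index date.  Notes enter the corpus only from the 730
days preceding the index date (half-open window: the index day itself is
excluded) and only from departments where patients first report cognitive
complaints; Neurology and Speech/Language Pathology are always excluded
because they see patients whose deficits are already known.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from datetime import date, timedelta
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .text_matcher import Note

logger = logging.getLogger(__name__)

LOOKBACK_DAYS = 730
DEFAULT_DEPARTMENTS = ("FamilyPractice", "BehavioralHealth")
EXCLUDED_DEPARTMENTS = frozenset({"Neurology", "SpeechLanguagePathology"})
CASI_POSITIVE_MAX = 85


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class InstrumentScore:
    instrument: str  # MMSE | MoCA | CASI
    score: int
    date: date

    def __post_init__(self) -> None:
        if self.instrument in ("MMSE", "MoCA") and not 0 <= self.score <= 30:
            raise ValueError(f"{self.instrument} score out of [0, 30]: {self.score}")
        if self.instrument == "CASI" and not 0 <= self.score <= 100:
            raise ValueError(f"CASI score out of [0, 100]: {self.score}")


@dataclass(frozen=True)
class CodedEvent:
    """A dated structured diagnosis or medication dispensing."""

    date: date
    kind: str  # diagnosis | medication
    code: str


@dataclass
class PatientRecord:
    patient_id: str
    birth_date: date
    sex: str  # F | M
    race: str = "White"
    ethnicity: str = "NotHispanic"
    enrollment_spans: list[tuple[date, date]] = field(default_factory=list)
    structured_codes: list[CodedEvent] = field(default_factory=list)
    scores: list[InstrumentScore] = field(default_factory=list)
    visit_dates: list[date] = field(default_factory=list)
    low_income: bool | None = None  # neighborhood income < $25,000 (None = missing)
    low_education: bool | None = None  # neighborhood < 25% college (None = missing)
    act_participant: bool = False

    def age_at(self, when: date) -> int:
        years = when.year - self.birth_date.year
        if (when.month, when.day) < (self.birth_date.month, self.birth_date.day):
            years -= 1
        if years < 0:
            raise ValueError(f"negative age for patient {self.patient_id} at {when}")
        return years

    def continuously_enrolled(self, start: date, end: date) -> bool:
        return any(s <= start and end <= e for s, e in self.enrollment_spans)


@dataclass
class CohortAssignment:
    patient_id: str
    index_date: date
    arm: str  # case | control
    matched_to: str | None = None
    cohort: str = "general"  # general | ACT
    split: str | None = None  # train | validation


def load_code_config(path: str | Path | None = None) -> dict[str, list[str]]:
    """Load the exclusion/indexing code lists (YAML mapping of category -> codes)."""
    if path is None:
        path = Path(str(resources.files("mciscreen.data").joinpath("exclusion_codes.yaml")))
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or not cfg:
        raise ConfigError(f"{path}: expected a mapping of category -> code list")
    required = {
        "mci_diagnosis", "adrd_diagnosis", "psychosis_diagnosis",
        "bipolar_diagnosis", "ad_medication", "antipsychotic_medication",
    }
    missing = required - cfg.keys()
    if missing:
        raise ConfigError(f"{path}: missing code categories: {sorted(missing)}")
    return {k: [str(c) for c in v] for k, v in cfg.items()}


def assign_index_dates(
    patients: Iterable[PatientRecord],
    mci_codes: Sequence[str],
    cohort: str = "general",
) -> dict[str, date]:
    """First qualifying event per patient: MCI diagnosis (general) or CASI <= 85 (ACT).

    Patients with no qualifying event are absent from the result — they form
    the control pool and inherit an index date if matched to a case.
    """
    out: dict[str, date] = {}
    code_set = set(mci_codes)
    for p in patients:
        if cohort == "ACT":
            dates = [s.date for s in p.scores
                     if s.instrument == "CASI" and s.score <= CASI_POSITIVE_MAX]
        else:
            dates = [e.date for e in p.structured_codes
                     if e.kind == "diagnosis" and e.code in code_set]
        if dates:
            out[p.patient_id] = min(dates)
    return out


def _quarter(d: date) -> tuple[int, int]:
    return d.year, (d.month - 1) // 3


def match_controls(
    cases: Mapping[str, date],
    case_patients: Mapping[str, PatientRecord],
    pool: Sequence[PatientRecord],
    seed: int = 0,
    age_band_years: int = 5,
) -> tuple[list[CohortAssignment], list[str]]:
    """Greedy randomized 1:1 matching of controls to cases.

    Controls must share sex, race, ethnicity and age band with the case at
    the case's index date, and have a health-care visit within the case's
    3-month calendar quarter.  Each control is used at most once; the control
    inherits the case's index date.  Returns (assignments for both arms,
    unmatched case ids).
    """
    rng = np.random.default_rng(seed)
    pool = list(pool)
    used: set[str] = set()
    assignments: list[CohortAssignment] = []
    unmatched: list[str] = []
    case_ids = sorted(cases)
    rng.shuffle(case_ids)
    for cid in case_ids:
        idx = cases[cid]
        cp = case_patients[cid]
        band = cp.age_at(idx) // age_band_years if age_band_years else cp.age_at(idx)
        q = _quarter(idx)
        eligible = [
            c for c in pool
            if c.patient_id not in used
            and c.sex == cp.sex
            and c.race == cp.race
            and c.ethnicity == cp.ethnicity
            and c.birth_date <= idx
            and (c.age_at(idx) // age_band_years if age_band_years else c.age_at(idx)) == band
            and any(_quarter(v) == q for v in c.visit_dates)
        ]
        if not eligible:
            unmatched.append(cid)
            continue
        pick = eligible[int(rng.integers(len(eligible)))]
        used.add(pick.patient_id)
        assignments.append(CohortAssignment(cid, idx, "case"))
        assignments.append(
            CohortAssignment(pick.patient_id, idx, "control", matched_to=cid)
        )
    if unmatched:
        logger.warning("%d cases unmatched", len(unmatched))
    return assignments, unmatched


@dataclass
class ExclusionTally:
    """Ordered record of how many patients each sequential filter removed."""

    steps: list[tuple[str, int]] = field(default_factory=list)
    n_input: int = 0
    n_retained: int = 0

    def add(self, name: str, removed: int) -> None:
        self.steps.append((name, removed))

    @property
    def total_removed(self) -> int:
        return sum(n for _, n in self.steps)


def apply_exclusions(
    patients: Sequence[PatientRecord],
    index_dates: Mapping[str, date],
    code_config: Mapping[str, Sequence[str]],
    notes: Sequence[Note] = (),
    lookback_days: int = LOOKBACK_DAYS,
) -> tuple[list[PatientRecord], ExclusionTally]:
    """Sequential eligibility filters over the lookback window before index.

    Order: continuous enrollment for the full lookback -> ADRD diagnosis ->
    psychosis -> prior MCI diagnosis -> bipolar disorder -> antipsychotic
    medication -> longitudinal-study overlap -> no notes in window.  The
    tally reports the count removed at each step; patients without an index
    date are dropped up front (they cannot be windowed).
    """
    if not code_config:
        raise ConfigError("exclusion code configuration is required")
    tally = ExclusionTally(n_input=len(patients))
    current = [p for p in patients if p.patient_id in index_dates]
    tally.add("no_index_date", len(patients) - len(current))

    notes_by_pid: dict[str, list[Note]] = defaultdict(list)
    for n in notes:
        notes_by_pid[n.patient_id].append(n)

    def window(p: PatientRecord) -> tuple[date, date]:
        idx = index_dates[p.patient_id]
        return idx - timedelta(days=lookback_days), idx

    def has_code(p: PatientRecord, kind: str, codes: Sequence[str]) -> bool:
        lo, hi = window(p)
        cs = set(codes)
        return any(
            e.kind == kind and e.code in cs and lo <= e.date < hi
            for e in p.structured_codes
        )

    steps: list[tuple[str, callable]] = [
        ("not_continuously_enrolled",
         lambda p: not p.continuously_enrolled(*window(p))),
        ("adrd_diagnosis", lambda p: has_code(p, "diagnosis", code_config["adrd_diagnosis"])),
        ("psychosis_diagnosis", lambda p: has_code(p, "diagnosis", code_config["psychosis_diagnosis"])),
        ("mci_diagnosis", lambda p: has_code(p, "diagnosis", code_config["mci_diagnosis"])),
        ("bipolar_diagnosis", lambda p: has_code(p, "diagnosis", code_config["bipolar_diagnosis"])),
        ("antipsychotic_medication",
         lambda p: has_code(p, "medication", code_config["antipsychotic_medication"])
         or has_code(p, "medication", code_config["ad_medication"])),
        ("act_overlap", lambda p: p.act_participant),
        ("no_notes_in_window",
         lambda p: not select_notes(notes_by_pid.get(p.patient_id, []),
                                    index_dates[p.patient_id],
                                    lookback_days=lookback_days)),
    ]
    for name, predicate in steps:
        kept = [p for p in current if not predicate(p)]
        tally.add(name, len(current) - len(kept))
        current = kept
    tally.n_retained = len(current)
    for name, n in tally.steps:
        logger.info("exclusion %s: removed %d", name, n)
    return current, tally


def select_notes(
    notes: Iterable[Note],
    index_date: date,
    departments: Sequence[str] = DEFAULT_DEPARTMENTS,
    lookback_days: int = LOOKBACK_DAYS,
) -> list[Note]:
    """Notes in ``[index - lookback, index)`` from allowed departments.

    Neurology and Speech/Language Pathology notes are excluded regardless of
    the allowed list.
    """
    lo = index_date - timedelta(days=lookback_days)
    allowed = set(departments) - EXCLUDED_DEPARTMENTS
    return [
        n for n in notes
        if lo <= n.service_date < index_date and n.department in allowed
    ]


def split_cohort(
    patient_ids: Sequence[str],
    train_fraction: float = 0.6,
    seed: int = 0,
) -> dict[str, str]:
    """Patient-level random train/validation split, reproducible under seed."""
    if not 0 <= train_fraction <= 1:
        raise ValueError("train_fraction must be in [0, 1]")
    ids = sorted(set(patient_ids))
    if len(ids) != len(patient_ids):
        raise ValueError("patient_ids must be unique")
    rng = np.random.default_rng(seed)
    order = list(ids)
    rng.shuffle(order)
    n_train = int(round(train_fraction * len(order)))
    return {pid: ("train" if i < n_train else "validation") for i, pid in enumerate(order)}
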