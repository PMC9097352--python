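from datetime import date, timedelta

import pytest

from mciscreen.cohort import (
    CodedEvent, CohortAssignment, ConfigError, InstrumentScore, PatientRecord,
    apply_exclusions, assign_index_dates, load_code_config, match_controls,
    select_notes, split_cohort,
)
from mciscreen.text_matcher import Note

from .conftest import make_note

IDX = date(2012, 6, 15)


def patient(pid="p1", age=75, sex="F", race="White", ethnicity="NotHispanic",
            codes=(), scores=(), visits=(), enrolled_from=date(2009, 1, 1),
            enrolled_to=date(2016, 1, 1), act=False):
    return PatientRecord(
        patient_id=pid,
        birth_date=IDX.replace(year=IDX.year - age) - timedelta(days=30),
        sex=sex, race=race, ethnicity=ethnicity,
        enrollment_spans=[(enrolled_from, enrolled_to)],
        structured_codes=list(codes), scores=list(scores),
        visit_dates=list(visits), act_participant=act,
    )


class TestInstrumentScore:
    @pytest.mark.parametrize("inst,bad", [("MMSE", 31), ("MoCA", -1), ("CASI", 101)])
    def test_range_validation(self, inst, bad):
        with pytest.raises(ValueError):
            InstrumentScore(inst, bad, IDX)


class TestAssignIndexDates:
    def test_first_structured_mci_diagnosis(self):
        p = patient(codes=[
            CodedEvent(date(2011, 1, 1), "diagnosis", "G31.84"),
            CodedEvent(date(2010, 3, 1), "diagnosis", "G31.84"),
        ])
        out = assign_index_dates([p], mci_codes=["G31.84"])
        assert out == {"p1": date(2010, 3, 1)}

    def test_act_first_positive_casi(self):
        p = patient(scores=[
            InstrumentScore("CASI", 90, date(2010, 1, 1)),
            InstrumentScore("CASI", 84, date(2012, 1, 1)),
        ])
        out = assign_index_dates([p], mci_codes=[], cohort="ACT")
        assert out == {"p1": date(2012, 1, 1)}

    def test_casi_86_is_negative(self):
        p = patient(scores=[InstrumentScore("CASI", 86, date(2010, 1, 1))])
        assert assign_index_dates([p], mci_codes=[], cohort="ACT") == {}

    def test_casi_85_boundary_is_positive(self):
        p = patient(scores=[InstrumentScore("CASI", 85, date(2010, 1, 1))])
        assert assign_index_dates([p], mci_codes=[], cohort="ACT") == {"p1": date(2010, 1, 1)}

    def test_no_qualifying_event_means_control_pool(self):
        assert assign_index_dates([patient()], mci_codes=["G31.84"]) == {}


class TestMatchControls:
    def test_single_eligible_control_inherits_index(self):
        case = patient("case1", visits=[IDX])
        ctrl = patient("ctrl1", visits=[date(2012, 5, 1)])  # same calendar quarter
        pairs, unmatched = match_controls(
            {"case1": IDX}, {"case1": case}, [ctrl], seed=0
        )
        assert unmatched == []
        by_arm = {a.arm: a for a in pairs}
        assert by_arm["control"].patient_id == "ctrl1"
        assert by_arm["control"].index_date == IDX
        assert by_arm["control"].matched_to == "case1"

    @pytest.mark.parametrize(
        "kw",
        [dict(sex="M"), dict(race="Black"), dict(ethnicity="Hispanic"),
         dict(age=85), dict(visits=[date(2012, 1, 5)])],
    )
    def test_mismatch_leaves_case_unmatched(self, kw):
        case = patient("case1", visits=[IDX])
        base = dict(visits=[date(2012, 5, 1)])
        base.update(kw)
        ctrl = patient("ctrl1", **base)
        pairs, unmatched = match_controls({"case1": IDX}, {"case1": case}, [ctrl], seed=0)
        assert pairs == [] and unmatched == ["case1"]

    def test_control_used_at_most_once(self):
        cases = {"c1": IDX, "c2": IDX}
        case_pats = {k: patient(k, visits=[IDX]) for k in cases}
        ctrl = patient("ctrl1", visits=[date(2012, 5, 1)])
        pairs, unmatched = match_controls(cases, case_pats, [ctrl], seed=0)
        assert len([a for a in pairs if a.arm == "case"]) == 1
        assert len(unmatched) == 1

    def test_empty_pool_warns_not_errors(self):
        pairs, unmatched = match_controls({"c1": IDX}, {"c1": patient("c1")}, [], seed=0)
        assert pairs == [] and unmatched == ["c1"]

    def test_seed_reproducible(self):
        cases = {"c1": IDX}
        cp = {"c1": patient("c1", visits=[IDX])}
        pool = [patient(f"x{i}", visits=[date(2012, 4, 2)]) for i in range(10)]
        a = match_controls(cases, cp, pool, seed=7)
        b = match_controls(cases, cp, pool, seed=7)
        assert a == b


class TestSelectNotes:
    def test_half_open_window(self):
        notes = [
            make_note("a", note_id="in", service_date=IDX - timedelta(days=730)),
            make_note("b", note_id="out", service_date=IDX),
        ]
        kept = select_notes(notes, IDX)
        assert [n.note_id for n in kept] == ["in"]

    def test_neurology_always_excluded(self):
        notes = [
            make_note("a", department="Neurology", service_date=IDX - timedelta(days=10)),
            make_note("b", department="SpeechLanguagePathology",
                      service_date=IDX - timedelta(days=10)),
        ]
        assert select_notes(notes, IDX) == []
        assert select_notes(notes, IDX, departments=("Neurology", "FamilyPractice")) == []

    def test_post_index_notes_flag_no_notes(self):
        notes = [make_note("a", service_date=IDX + timedelta(days=5))]
        assert select_notes(notes, IDX) == []

    def test_pure_filter_order_invariant(self):
        notes = [make_note(str(i), note_id=f"n{i}",
                           service_date=IDX - timedelta(days=i * 100))
                 for i in range(1, 9)]
        a = {n.note_id for n in select_notes(notes, IDX)}
        b = {n.note_id for n in select_notes(list(reversed(notes)), IDX)}
        assert a == b


class TestApplyExclusions:
    @pytest.fixture
    def codes(self):
        return load_code_config()

    def test_donepezil_in_lookback_excluded(self, codes):
        p = patient(codes=[CodedEvent(IDX - timedelta(days=365), "medication", "donepezil")])
        notes = [make_note("x", service_date=IDX - timedelta(days=30))]
        kept, tally = apply_exclusions([p], {"p1": IDX}, codes, notes=notes)
        assert kept == []
        assert dict(tally.steps)["antipsychotic_medication"] == 1

    def test_adrd_outside_lookback_retained(self, codes):
        p = patient(codes=[CodedEvent(IDX - timedelta(days=3 * 365), "diagnosis", "F03")])
        notes = [make_note("x", service_date=IDX - timedelta(days=30))]
        kept, _ = apply_exclusions([p], {"p1": IDX}, codes, notes=notes)
        assert [q.patient_id for q in kept] == ["p1"]

    def test_sequential_order_and_tally_sums(self, codes):
        mk = lambda pid, **kw: patient(pid, **kw)
        note_for = lambda pid: make_note("t", patient_id=pid,
                                         service_date=IDX - timedelta(days=30))
        pats = [
            mk("keep"),
            mk("enroll", enrolled_from=IDX - timedelta(days=100)),
            mk("adrd", codes=[CodedEvent(IDX - timedelta(days=10), "diagnosis", "F03")]),
            mk("psych", codes=[CodedEvent(IDX - timedelta(days=10), "diagnosis", "F29")]),
            mk("mci", codes=[CodedEvent(IDX - timedelta(days=10), "diagnosis", "G31.84")]),
            mk("bipolar", codes=[CodedEvent(IDX - timedelta(days=10), "diagnosis", "F31.9")]),
            mk("meds", codes=[CodedEvent(IDX - timedelta(days=10), "medication", "haloperidol")]),
            mk("act", act=True),
            mk("nonotes"),
            # carries both ADRD and psychosis: must be counted once, at the
            # earlier (ADRD) step
            mk("both", codes=[CodedEvent(IDX - timedelta(days=10), "diagnosis", "F03"),
                              CodedEvent(IDX - timedelta(days=10), "diagnosis", "F29")]),
        ]
        notes = [note_for(p.patient_id) for p in pats if p.patient_id != "nonotes"]
        index = {p.patient_id: IDX for p in pats}
        kept, tally = apply_exclusions(pats, index, codes, notes=notes)
        assert [p.patient_id for p in kept] == ["keep"]
        steps = dict(tally.steps)
        assert steps["adrd_diagnosis"] == 2  # "adrd" and "both"
        assert steps["psychosis_diagnosis"] == 1
        assert [s for s, _ in tally.steps] == [
            "no_index_date", "not_continuously_enrolled", "adrd_diagnosis",
            "psychosis_diagnosis", "mci_diagnosis", "bipolar_diagnosis",
            "antipsychotic_medication", "act_overlap", "no_notes_in_window",
        ]
        assert tally.n_input - tally.n_retained == tally.total_removed

    def test_missing_code_config_is_hard_error(self):
        with pytest.raises(ConfigError):
            apply_exclusions([patient()], {"p1": IDX}, {}, notes=[])

    def test_incomplete_code_config_file(self, tmp_path):
        f = tmp_path / "codes.yaml"
        f.write_text("mci_diagnosis: [X]\n")
        with pytest.raises(ConfigError, match="missing"):
            load_code_config(f)


class TestSplitCohort:
    def test_exact_fraction_small(self):
        split = split_cohort([f"p{i}" for i in range(10)], 0.6, seed=0)
        assert sum(v == "train" for v in split.values()) == 6
        assert sum(v == "validation" for v in split.values()) == 4

    def test_seed_reproducible_and_disjoint(self):
        ids = [f"p{i}" for i in range(101)]
        a = split_cohort(ids, 0.6, seed=3)
        b = split_cohort(ids, 0.6, seed=3)
        assert a == b
        assert set(a) == set(ids)

    def test_published_cohort_sizes(self):
        # 2391 patients at a 60% training fraction -> 1435 train / 956 validation
        split = split_cohort([f"p{i}" for i in range(2391)], 0.6, seed=0)
        n_train = sum(v == "train" for v in split.values())
        assert abs(n_train - 1435) <= 1
        assert abs((2391 - n_train) - 956) <= 1

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            split_cohort(["a", "a", "b"], 0.6, seed=0)
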