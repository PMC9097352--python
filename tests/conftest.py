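from datetime import date

import numpy as np
import pytest

from mciscreen.dictionary import load_bundled_dictionary
from mciscreen.text_matcher import Note


@pytest.fixture(scope="session")
def full_dict():
    return load_bundled_dictionary("mci")


@pytest.fixture(scope="session")
def toy_dict():
    return load_bundled_dictionary("toy")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_note(text, note_id="n1", patient_id="p1", department="FamilyPractice",
              service_date=date(2010, 6, 1)):
    return Note(note_id=note_id, patient_id=patient_id, department=department,
                service_date=service_date, text=text)


@pytest.fixture
def note_factory():
    return make_note
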