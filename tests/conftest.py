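import datetime as dt

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from dmfind import (ClinicalNote, GeneratorConfig, TrainingConfig,
                    default_knowledge_base, generate_corpus)


@pytest.fixture(scope="session")
def kb():
    return default_knowledge_base()


@pytest.fixture(scope="session")
def small_corpus():
    """A seeded 400-patient synthetic corpus shared across tests."""
    config = GeneratorConfig(n_patients=400, seed=42)
    notes, truth = generate_corpus(config)
    return notes, truth, config


@pytest.fixture(scope="session")
def fitted_results(small_corpus, kb):
    """A model fitted (with oracle refinement) on the small corpus."""
    from dmfind import DMCaseFinder, truth_oracle_from

    notes, truth, _ = small_corpus
    model = DMCaseFinder(notes, kb=kb,
                         config=TrainingConfig(seed=0, n_trees=100))
    return model.fit(truth_oracle=truth_oracle_from(truth)), notes, truth


def make_note(text, *, note_id="n1", patient_id="p1", date="2014-01-15",
              icd_codes=(), age=55.0, sex="female", facility="F0"):
    return ClinicalNote(note_id=note_id, patient_id=patient_id,
                        encounter_date=dt.date.fromisoformat(date),
                        facility_id=facility, note_type="progress note",
                        text=text, icd_codes=tuple(icd_codes), age=age, sex=sex)
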