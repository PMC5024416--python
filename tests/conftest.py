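"""Shared fixtures: handcrafted worked-example record and generated cohorts."""

from __future__ import annotations

import datetime as dt

import pytest
from hypothesis import settings

from oncophen import ScenarioConfig, generate, run_pipeline
from oncophen.lexicon import default_lexicon
from oncophen.model import (ClinicalDocument, CodedValue, ConceptRef,
                            DocType, Mention, PatientRecord, Polarity)

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")


def make_mention(code: str, doc_id: str, n: int, *, value=None,
                 polarity: Polarity = Polarity.affirmed,
                 pid: str = "pt1") -> Mention:
    """Build a mention of a lexicon concept with a synthetic span."""
    concept = default_lexicon()[code]
    begin = 40 * n
    return Mention(
        id=f"men:{pid}:{doc_id}:{n}", document_id=doc_id,
        span=(begin, begin + len(concept.label)), text=concept.label,
        concept=ConceptRef(code=concept.code, label=concept.label,
                           semantic_class=concept.semantic_class),
        polarity=polarity, value=value)


def make_document(doc_id: str, date: dt.date, doc_type: DocType,
                  codes: list, pid: str = "pt1") -> ClinicalDocument:
    """Build a document from (code, value) pairs or bare codes."""
    mentions = []
    for n, item in enumerate(codes, start=1):
        code, value = item if isinstance(item, tuple) else (item, None)
        mentions.append(make_mention(code, doc_id, n, value=value, pid=pid))
    return ClinicalDocument(id=doc_id, patient_id=pid, date=date,
                            doc_type=doc_type, mentions=mentions)


@pytest.fixture
def worked_example_record() -> PatientRecord:
    """A four-document breast-cancer record.

    Documents 1-3 carry the diagnostic workup (mammogram, mass, needle
    biopsy, invasive ductal carcinoma, T1, N0, M0, BRCA status); document 4
    carries the metastatic workup (MRI, enhancing lesion, metastatic
    carcinoma).
    """
    d = dt.date
    docs = [
        make_document("d1", d(2011, 3, 1), DocType.radiology,
                      ["C16818", "C25315"]),
        make_document("d2", d(2011, 3, 10), DocType.pathology,
                      ["C15361", "C25315"]),
        make_document("d3", d(2011, 3, 20), DocType.pathology,
                      ["C4194",
                       ("C48885", CodedValue(code="T1")),
                       ("C48884", CodedValue(code="N0")),
                       ("C48883", CodedValue(code="M0")),
                       ("C900220", CodedValue(code="negative"))]),
        make_document("d4", d(2011, 9, 5), DocType.radiology,
                      ["C16809", "C120180", "C36263"]),
    ]
    return PatientRecord(patient_id="pt1", documents=docs)


def zero_noise_config(seed: int, scenario: str,
                      n_patients: int = 2, **kw) -> ScenarioConfig:
    params = {"duplication_rate": 0.0, "negation_rate": 0.0,
              "conflict_rate": 0.0, **kw}
    return ScenarioConfig(seed=seed, scenario=scenario,
                          n_patients=n_patients, **params)


@pytest.fixture(scope="session")
def summarized_cohort() -> list:
    """A mixed summarized cohort with its generator ground truths."""
    out = []
    for scenario, seed, death in [("primary_only", 11, 0.0),
                                  ("primary_then_metastasis", 12, 0.5),
                                  ("treated_with_recurrence", 13, 0.5)]:
        cfg = ScenarioConfig(seed=seed, scenario=scenario, n_patients=4,
                             death_rate=death, death_gap_days=7)
        for i, patient in enumerate(generate(cfg)):
            record = patient.record()
            record.patient_id = f"{scenario}:{patient.patient_id}"
            for doc in record.documents:
                doc.patient_id = record.patient_id
            out.append((run_pipeline(record), patient.truth))
    return out
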