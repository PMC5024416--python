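"""Synthetic patient-record generator with ground truth.

Generates mention files with the structure the pipeline assumes — a dated
document sequence whose mentions encode a breast-cancer scenario
(mammogram → mass → biopsy → carcinoma diagnosis → TNM/receptor panel →
treatment → metastasis or recurrence) — together with the intended episode
list and phenotype attribute values, so every pipeline stage is testable
without clinical data.

Three scenarios are bundled:

* ``primary_only`` — a three-document diagnostic workup;
* ``primary_then_metastasis`` — the same workup followed by a radiology
  document with MRI, enhancing lesion and metastatic carcinoma findings;
* ``treated_with_recurrence`` — workup, two treatment documents, then a
  recurrent-carcinoma diagnosis.

All randomness flows through one seeded generator, and mention files are
written with sorted keys, so a seed reproduces its output byte for byte.
The generator emits only structured mention output, not narrative text.
"""

from __future__ import annotations

import datetime as _dt
import json
from enum import Enum
from pathlib import Path
from typing import Any, Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator

from .ingest import write_mention_file
from .lexicon import Lexicon, default_lexicon
from .model import (ClinicalDocument, CodedValue, ConceptRef, DocTimeRel,
                    DocType, Mention, PatientRecord, Polarity, QuantityValue,
                    Value)

__all__ = ["Scenario", "ScenarioConfig", "GeneratedPatient", "generate",
           "write_patient_files", "PerturbConfig", "perturb"]

_EPOCH = _dt.date(2010, 1, 5)

_MET_SITES = ["C12392", "C12366", "C12439", "C12468"]  # liver, bone, brain, lung
_DISTRACTORS = ["C21243", "C94774"]  # lymphadenopathy, skin thickening
_COMORBIDITIES = ["C3117", "C26747"]

_STAGE_MAP = {("T1", "N0"): "Stage I", ("T2", "N0"): "Stage IIA",
              ("T1", "N1"): "Stage IIA", ("T2", "N1"): "Stage IIB",
              ("T3", "N0"): "Stage IIB", ("T3", "N1"): "Stage IIIA"}


class Scenario(str, Enum):
    primary_only = "primary_only"
    primary_then_metastasis = "primary_then_metastasis"
    treated_with_recurrence = "treated_with_recurrence"


class ScenarioConfig(BaseModel):
    """Generator configuration; all rates are probabilities in [0, 1]."""

    seed: int = 0
    n_patients: int = 10
    scenario: Scenario = Scenario.primary_then_metastasis
    #: per-mention probability of emitting a duplicate mention of the same
    #: concept elsewhere in the document.
    duplication_rate: float = 0.3
    #: per-document probability of adding a negated distractor mention.
    negation_rate: float = 0.1
    #: probability that a HER2 FISH result is added that disagrees with the
    #: IHC result (the FISH value is then the ground truth).
    conflict_rate: float = 0.1
    #: probability a patient record ends with a death document.
    death_rate: float = 0.0
    #: days between the last clinical document and the death document.
    death_gap_days: int = 35
    #: number of distinct metastatic sites in metastasis documents.
    n_met_sites: int = 1
    #: nominal inter-document gap (jittered ±3 days).
    doc_gap_days: int = 14
    #: range (inclusive) of extra comorbidity progress notes per patient.
    extra_notes: tuple[int, int] = (0, 1)
    prevalence: dict[str, float] = Field(default_factory=lambda: {
        "er_positive": 0.75, "pr_positive": 0.65, "her2_positive": 0.2,
        "brca1_positive": 0.1, "lobular": 0.2, "in_situ": 0.15,
    })

    @field_validator("duplication_rate", "negation_rate", "conflict_rate",
                     "death_rate")
    @classmethod
    def _rate(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
        return v

    @field_validator("prevalence")
    @classmethod
    def _prev(cls, v: dict[str, float]) -> dict[str, float]:
        for key, p in v.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence {key!r} must lie in [0, 1]")
        return v


class GeneratedPatient(BaseModel):
    """One generated patient: documents plus the intended ground truth."""

    patient_id: str
    documents: list[ClinicalDocument]
    truth: dict[str, Any]

    def record(self) -> PatientRecord:
        return PatientRecord(patient_id=self.patient_id,
                             documents=[d.model_copy(deep=True)
                                        for d in self.documents])


class _DocBuilder:
    """Accumulates mentions of one document with synthetic spans."""

    def __init__(self, pid: str, index: int, date: _dt.date,
                 doc_type: DocType, lexicon: Lexicon,
                 rng: np.random.Generator, duplication_rate: float) -> None:
        self.doc_id = f"doc:{pid}:{index:02d}"
        self.pid = pid
        self.date = date
        self.doc_type = doc_type
        self._lex = lexicon
        self._rng = rng
        self._dup = duplication_rate
        self._offset = 0
        self._n = 0
        self.mentions: list[Mention] = []

    def add(self, code: str, value: Optional[Value] = None,
            polarity: Polarity = Polarity.affirmed,
            duplicable: bool = True) -> None:
        concept = self._lex[code]
        self._emit(concept, value, polarity)
        if duplicable and self._rng.random() < self._dup:
            self._emit(concept, value, polarity)

    def _emit(self, concept, value, polarity) -> None:
        self._n += 1
        text = concept.label
        begin = self._offset
        self._offset += len(text) + 2
        self.mentions.append(Mention(
            id=f"men:{self.pid}:{self.doc_id.rsplit(':', 1)[1]}:{self._n}",
            document_id=self.doc_id,
            span=(begin, begin + len(text)), text=text,
            concept=ConceptRef(code=concept.code, label=concept.label,
                               semantic_class=concept.semantic_class),
            polarity=polarity, doc_time_rel=DocTimeRel.OVERLAP, value=value))

    def build(self) -> ClinicalDocument:
        return ClinicalDocument(id=self.doc_id, patient_id=self.pid,
                                date=self.date, doc_type=self.doc_type,
                                mentions=self.mentions)


def _coded(code: str) -> CodedValue:
    return CodedValue(code=code)


def _generate_patient(pid: str, config: ScenarioConfig,
                      rng: np.random.Generator,
                      lexicon: Lexicon) -> GeneratedPatient:
    prev = config.prevalence
    lobular = rng.random() < prev.get("lobular", 0.2)
    in_situ = (config.scenario is Scenario.primary_only
               and rng.random() < prev.get("in_situ", 0.15))
    dx_code = {(False, False): "C4194", (True, False): "C4018",
               (False, True): "C2924", (True, True): "C4019"}[(lobular, in_situ)]
    if in_situ:
        t_val, n_val, stage = "Tis", "N0", "Stage 0"
    else:
        t_val = str(rng.choice(["T1", "T2", "T3"], p=[0.5, 0.35, 0.15]))
        n_val = str(rng.choice(["N0", "N1"], p=[0.7, 0.3]))
        stage = _STAGE_MAP[(t_val, n_val)]
    m_val = "M0"
    er = "positive" if rng.random() < prev.get("er_positive", 0.75) else "negative"
    pr = "positive" if rng.random() < prev.get("pr_positive", 0.65) else "negative"
    her2_ihc = ("positive" if rng.random() < prev.get("her2_positive", 0.2)
                else "negative")
    conflict = rng.random() < config.conflict_rate
    her2_fish = ({"positive": "negative",
                  "negative": "positive"}[her2_ihc] if conflict else None)
    brca1 = ("positive" if rng.random() < prev.get("brca1_positive", 0.1)
             else "negative")
    size_cm = round(float(rng.uniform(0.8, 4.5)), 1)
    nottingham = int(rng.integers(3, 10))

    date = _EPOCH + _dt.timedelta(days=int(rng.integers(0, 180)))

    def _gap() -> _dt.timedelta:
        return _dt.timedelta(days=config.doc_gap_days
                             + int(rng.integers(-3, 4)))

    docs: list[_DocBuilder] = []
    idx = 0

    def _doc(doc_type: DocType, when: _dt.date) -> _DocBuilder:
        nonlocal idx
        idx += 1
        b = _DocBuilder(pid, idx, when, doc_type, lexicon, rng,
                        config.duplication_rate)
        docs.append(b)
        return b

    # comorbidity notes precede the workup
    comorbidities = []
    for _ in range(int(rng.integers(config.extra_notes[0],
                                    config.extra_notes[1] + 1))):
        code = str(rng.choice(_COMORBIDITIES))
        comorbidities.append(code)
        note = _doc(DocType.progress_note, date)
        note.add(code)
        date += _gap()

    # diagnostic workup: imaging -> biopsy -> pathology panel
    d1 = _doc(DocType.radiology, date)
    d1.add("C16818")           # mammography
    d1.add("C25315")           # mass
    date += _gap()
    d2 = _doc(DocType.pathology, date)
    d2.add("C15361")           # core needle biopsy
    d2.add("C25315")
    date += _gap()
    d3 = _doc(DocType.pathology, date)
    d3.add(dx_code)
    d3.add("C12971")           # breast
    d3.add("C48885", _coded(t_val), duplicable=False)
    d3.add("C48884", _coded(n_val), duplicable=False)
    d3.add("C48883", _coded(m_val), duplicable=False)
    d3.add("C28074", _coded(stage), duplicable=False)
    d3.add("C900210", _coded(er), duplicable=False)
    d3.add("C900211", _coded(pr), duplicable=False)
    d3.add("C900212", _coded(her2_ihc), duplicable=False)
    if her2_fish is not None:
        d3.add("C900213", _coded(her2_fish), duplicable=False)
    d3.add("C900220", _coded(brca1), duplicable=False)
    d3.add("C900230", QuantityValue(value=size_cm, unit="cm"),
           duplicable=False)
    d3.add("C900231", QuantityValue(value=float(nottingham), unit="points"),
           duplicable=False)

    episodes = [("PrimaryTumor", "Diagnostic")]
    treatments: list[str] = []
    met_sites: list[str] = []

    if config.scenario is Scenario.treated_with_recurrence:
        date += _gap()
        d4 = _doc(DocType.progress_note, date)
        d4.add("C456")         # doxorubicin
        d4.add("C15755")       # lumpectomy
        date += _gap()
        d5 = _doc(DocType.progress_note, date)
        hormonal = er == "positive"
        d5.add("C855" if hormonal else "C1411")
        treatments = sorted(["C456", "C15755", "C855" if hormonal else "C1411"])
        date += _gap()
        d6 = _doc(DocType.pathology, date)
        d6.add("C7771")        # recurrent breast carcinoma
        episodes += [("PrimaryTumor", "Treatment"), ("Recurrence", "Diagnostic")]
    elif config.scenario is Scenario.primary_then_metastasis:
        date += _gap()
        d4 = _doc(DocType.radiology, date)
        d4.add("C16809")       # MRI
        d4.add("C120180")      # enhancing lesion
        d4.add("C36263")       # metastatic carcinoma
        met_sites = sorted(
            str(c) for c in rng.choice(_MET_SITES,
                                       size=min(config.n_met_sites,
                                                len(_MET_SITES)),
                                       replace=False))
        for site in met_sites:
            d4.add(site, duplicable=False)
        episodes.append(("MetastaticTumor", "Diagnostic"))

    date_of_death = None
    if rng.random() < config.death_rate:
        date += _dt.timedelta(days=config.death_gap_days)
        dd = _doc(DocType.discharge_summary, date)
        dd.add("C28554", duplicable=False)
        date_of_death = date.isoformat()

    # negated distractor mentions (never part of the ground truth)
    for b in docs:
        if rng.random() < config.negation_rate:
            b.add(str(rng.choice(_DISTRACTORS)), polarity=Polarity.negated,
                  duplicable=False)

    her2 = her2_fish if her2_fish is not None else her2_ihc
    tumors: list[dict[str, Any]] = []
    if config.scenario is Scenario.primary_then_metastasis:
        for site in met_sites:
            tumors.append({"episode_type": "MetastaticTumor",
                           "body_site": site, "cancer_type": "carcinoma",
                           "histologic_type": None,
                           "tumor_extent": "metastatic",
                           "manifestations": {}})
    tumors.append({
        "episode_type": "PrimaryTumor", "body_site": "C12971",
        "cancer_type": "carcinoma",
        "histologic_type": "lobular" if lobular else "ductal",
        "tumor_extent": "in-situ" if in_situ else "invasive",
        "manifestations": {"er_status": er, "pr_status": pr,
                           "her2_status": her2,
                           "tumor_size": {"value": size_cm, "unit": "cm"},
                           "nottingham_score": {"value": float(nottingham),
                                                "unit": "points"}}})
    if config.scenario is Scenario.treated_with_recurrence:
        tumors.append({"episode_type": "Recurrence", "body_site": "C12971",
                       "cancer_type": "carcinoma", "histologic_type": None,
                       "tumor_extent": None, "manifestations": {}})

    truth = {
        "patient_id": pid,
        "scenario": config.scenario.value,
        "episodes": episodes,
        "cancer": {
            "cancer_type": "carcinoma",
            "histologic_type": "lobular" if lobular else "ductal",
            "tumor_extent": "in-situ" if in_situ else "invasive",
            "cancer_stage": stage, "t_classification": t_val,
            "n_classification": n_val, "m_classification": m_val,
            "manifestations": {"brca1_status": brca1},
        },
        "tumors": tumors,
        "treatments": treatments,
        "comorbidities": sorted(set(comorbidities)),
        "date_of_death": date_of_death,
        "her2_conflict": conflict,
    }
    return GeneratedPatient(patient_id=pid,
                            documents=[b.build() for b in docs], truth=truth)


def generate(config: ScenarioConfig,
             lexicon: Optional[Lexicon] = None) -> list[GeneratedPatient]:
    """Generate ``config.n_patients`` synthetic patients, deterministically."""
    lexicon = lexicon or default_lexicon()
    rng = np.random.default_rng(config.seed)
    return [_generate_patient(f"pt{i + 1:03d}", config, rng, lexicon)
            for i in range(config.n_patients)]


def write_patient_files(patients: list[GeneratedPatient], out_dir) -> None:
    """Write per-patient mention files and ground-truth JSON under a directory."""
    out = Path(out_dir)
    for patient in patients:
        pdir = out / patient.patient_id
        pdir.mkdir(parents=True, exist_ok=True)
        for doc in patient.documents:
            write_mention_file(doc, pdir / (doc.id.replace(":", "_") + ".json"))
        with open(pdir / "ground_truth.json", "w", encoding="utf-8") as fh:
            json.dump(patient.truth, fh, sort_keys=True, indent=2)
            fh.write("\n")


# --------------------------------------------------------------------------
# Ground-truth comparison
# --------------------------------------------------------------------------

def _manifestation_values(phenotypes: list) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for phen in phenotypes:
        for a in phen.assertions:
            if not a.attribute.startswith("manifestation:"):
                continue
            name = a.attribute.split(":", 1)[1]
            v = a.value
            if isinstance(v, dict) and v.get("kind") == "coded":
                out[name] = v["code"]
            elif isinstance(v, dict) and v.get("kind") == "quantity":
                out[name] = {"value": v["value"], "unit": v["unit"]}
            else:
                out[name] = v
    return out


def _latest(phenotypes: list, attr: str) -> Any:
    value = None
    for phen in phenotypes:
        v = getattr(phen, attr, None)
        if v is not None:
            value = v
    return value


def recovered_truth(record: PatientRecord) -> dict[str, Any]:
    """Summarize a pipelined record in the generator's ground-truth shape.

    Used to check end-to-end recovery: on zero-noise generator output this
    must equal the ``truth`` dict of the generated patient (minus its
    bookkeeping keys).
    """
    episodes = sorted(
        ((ep.episode_type.value, ep.phase.value if ep.phase else None,
          ep.start_date) for ep in (record.course.leaf_episodes()
                                    if record.course else [])),
        key=lambda r: (r[2], r[0]))
    out: dict[str, Any] = {
        "patient_id": record.patient_id,
        "episodes": [[t, p] for t, p, _ in episodes],
        "cancer": None, "tumors": [], "treatments": [],
        "comorbidities": [], "date_of_death": None,
    }
    summary = record.summary
    if summary is None:
        return out
    attrs = summary.patient_attributes
    out["date_of_death"] = attrs.get("date_of_death")
    out["comorbidities"] = sorted(c["code"]
                                  for c in attrs.get("comorbidities", []))
    if not summary.cancers:
        return out
    cancer = summary.cancers[0]
    out["cancer"] = {
        "cancer_type": _latest(cancer.phenotypes, "cancer_type"),
        "histologic_type": _latest(cancer.phenotypes, "histologic_type"),
        "tumor_extent": _latest(cancer.phenotypes, "tumor_extent"),
        "cancer_stage": _latest(cancer.phenotypes, "cancer_stage"),
        "t_classification": _latest(cancer.phenotypes, "t_classification"),
        "n_classification": _latest(cancer.phenotypes, "n_classification"),
        "m_classification": _latest(cancer.phenotypes, "m_classification"),
        "manifestations": _manifestation_values(cancer.phenotypes),
    }
    for tumor in cancer.tumors:
        out["tumors"].append({
            "episode_type": tumor.episode_type.value,
            "body_site": tumor.body_site.code if tumor.body_site else None,
            "cancer_type": _latest(tumor.phenotypes, "cancer_type"),
            "histologic_type": _latest(tumor.phenotypes, "histologic_type"),
            "tumor_extent": _latest(tumor.phenotypes, "tumor_extent"),
            "manifestations": _manifestation_values(tumor.phenotypes),
        })
    out["treatments"] = sorted(t.concept.code for t in cancer.treatments)
    return out


def truth_for_comparison(truth: dict[str, Any]) -> dict[str, Any]:
    """Strip generator bookkeeping keys, leaving the recoverable subset."""
    keep = {"patient_id", "episodes", "cancer", "tumors", "treatments",
            "comorbidities", "date_of_death"}
    out = {k: v for k, v in truth.items() if k in keep}
    out["episodes"] = [list(e) for e in out.get("episodes", [])]
    return out


# --------------------------------------------------------------------------
# Noise injection
# --------------------------------------------------------------------------

class PerturbConfig(BaseModel):
    """Noise configuration for :func:`perturb`; zero everywhere = identity."""

    seed: int = 0
    #: per-mention probability of adding a negated duplicate mention.
    negated_duplicate_rate: float = 0.0
    #: probability of adding a discordant HER2 FISH result next to an
    #: existing IHC result (the summarizer must then prefer the FISH value).
    conflict_rate: float = 0.0
    #: per-mention probability of unanchoring the mention from its document
    #: date (doc_time_rel becomes BEFORE).
    unanchor_rate: float = 0.0

    @field_validator("negated_duplicate_rate", "conflict_rate",
                     "unanchor_rate")
    @classmethod
    def _rate(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
        return v


def perturb(record: PatientRecord, noise: PerturbConfig) -> PatientRecord:
    """Return a noisy copy of a documents-only record; schema validity holds.

    Injected noise: negated duplicate mentions of observed concepts,
    discordant HER2 IHC/FISH pairs, and unanchored document-time relations.
    With all rates zero the copy is identical to the input.
    """
    rng = np.random.default_rng(noise.seed)
    documents = []
    for doc in record.documents:
        mentions = [m.model_copy(deep=True) for m in doc.mentions]
        offset = max((m.span[1] for m in mentions), default=0) + 2
        extra: list[Mention] = []
        n = 0
        for m in mentions:
            if noise.unanchor_rate and rng.random() < noise.unanchor_rate:
                m.doc_time_rel = DocTimeRel.BEFORE
            if (noise.negated_duplicate_rate
                    and rng.random() < noise.negated_duplicate_rate):
                n += 1
                text = m.concept.label
                extra.append(m.model_copy(update={
                    "id": f"{m.id}_negdup{n}",
                    "span": (offset, offset + len(text)),
                    "polarity": Polarity.negated,
                    "doc_time_rel": DocTimeRel.OVERLAP}))
                offset += len(text) + 2
            if (noise.conflict_rate and m.concept.code == "C900212"
                    and isinstance(m.value, CodedValue)
                    and rng.random() < noise.conflict_rate):
                has_fish = any(x.concept.code == "C900213"
                               for x in mentions + extra)
                if not has_fish:
                    n += 1
                    label = "HER2/neu Status by FISH"
                    flipped = {"positive": "negative",
                               "negative": "positive"}.get(m.value.code)
                    if flipped:
                        extra.append(Mention(
                            id=f"{m.id}_fish{n}", document_id=doc.id,
                            span=(offset, offset + len(label)), text=label,
                            concept=ConceptRef(code="C900213", label=label,
                                               semantic_class="Observation"),
                            polarity=Polarity.affirmed,
                            value=CodedValue(code=flipped)))
                        offset += len(label) + 2
        mentions = sorted(mentions + extra,
                          key=lambda m: (m.span[0], m.span[1], m.id))
        documents.append(doc.model_copy(update={"mentions": mentions}))
    return PatientRecord(patient_id=record.patient_id, documents=documents)
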