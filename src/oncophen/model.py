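"""Domain types for the four-level cancer-phenotype model.

The model represents clinical information at increasing levels of
abstraction:

* **Level 1 — mentions**: span-anchored coded annotations extracted from one
  clinical document (concept, polarity, document-time relation).
* **Level 2 — compositions**: per-document summaries whose merged *event
  details* are typed by a six-member FHIR resource subset (Condition,
  Patient, Observation, BodySite, Procedure, MedicationStatement).
* **Level 3 — episodes**: clinically meaningful intervals (episode type ×
  phase), hierarchical and possibly overlapping, ordered into a disease
  course timeline.
* **Level 4 — phenotypes**: time-scoped attribute bundles (cancer type,
  histology, extent, stage, TNM, manifestations) attached to Cancer and
  Tumor entities.

Every object above Level 1 is linked to its sources through a central
provenance graph of ``wasDerivedFrom`` edges, so any summarized assertion
can be traced back to the mentions that support it.

Identifiers are opaque strings namespaced by level prefix (``men:``,
``doc:``, ``evt:``, ``epi:``, ``phe:``, ``tum:``, ``can:``, ``trt:``,
``out:``, ``var:``), which makes level membership decidable from the id
alone.
"""

from __future__ import annotations

import datetime as _dt
import json
import re
from enum import Enum
from typing import Any, Iterable, Literal, Optional, Union

import networkx as nx
from pydantic import BaseModel, Field, field_validator

from .lexicon import Lexicon, default_lexicon

__all__ = [
    "SemanticClass", "Polarity", "Uncertainty", "DocTimeRel", "ResourceKind",
    "DocType", "EpisodeType", "Phase", "ManifestationKind", "VariationScope",
    "TreatmentIntent", "ConceptRef", "CodedValue", "QuantityValue",
    "TextValue", "Value", "Period", "Mention", "ClinicalDocument",
    "EventDetail", "Composition", "Episode", "DiseaseCourse", "Manifestation",
    "Assertion", "TumorPhenotype", "CancerPhenotype", "Tumor", "Cancer",
    "Treatment", "Outcome", "SequenceVariation", "PatientSummary",
    "ProvenanceGraph", "PatientRecord", "CycleError", "NotFoundError",
    "validate_record", "derivation_closure", "derivation_path",
    "SEQUENCE_VARIANT_XREF",
]

#: Sequence Ontology cross-reference attached to every sequence variation.
SEQUENCE_VARIANT_XREF = "SO:0001060"


class CycleError(ValueError):
    """Raised when a provenance edge would create a derivation cycle."""


class NotFoundError(KeyError):
    """Raised when an identifier is not present in a provenance graph."""


# --------------------------------------------------------------------------
# Enumerations
# --------------------------------------------------------------------------

class SemanticClass(str, Enum):
    Condition = "Condition"
    Procedure = "Procedure"
    Medication = "Medication"
    Observation = "Observation"
    AnatomicalSite = "AnatomicalSite"


class Polarity(str, Enum):
    affirmed = "affirmed"
    negated = "negated"


class Uncertainty(str, Enum):
    certain = "certain"
    uncertain = "uncertain"


class DocTimeRel(str, Enum):
    """Temporal relation of an event to its document's creation time."""

    BEFORE = "BEFORE"
    OVERLAP = "OVERLAP"
    AFTER = "AFTER"
    BEFORE_OVERLAP = "BEFORE_OVERLAP"


class ResourceKind(str, Enum):
    """The six-member FHIR DSTU2 resource subset used for event details."""

    Condition = "Condition"
    Patient = "Patient"
    Observation = "Observation"
    BodySite = "BodySite"
    Procedure = "Procedure"
    MedicationStatement = "MedicationStatement"


class DocType(str, Enum):
    radiology = "radiology"
    pathology = "pathology"
    progress_note = "progress_note"
    discharge_summary = "discharge_summary"
    other = "other"


class EpisodeType(str, Enum):
    PrimaryTumor = "PrimaryTumor"
    MetastaticTumor = "MetastaticTumor"
    #: Recurrence is a configurable extension beyond the two core types.
    Recurrence = "Recurrence"


class Phase(str, Enum):
    Diagnostic = "Diagnostic"
    Treatment = "Treatment"
    FollowUp = "FollowUp"


class ManifestationKind(str, Enum):
    Clinical = "Clinical"
    Molecular = "Molecular"


class VariationScope(str, Enum):
    germline = "germline"
    tumor = "tumor"


class TreatmentIntent(str, Enum):
    adjuvant = "adjuvant"
    neoadjuvant = "neoadjuvant"
    palliative = "palliative"
    unknown = "unknown"


# --------------------------------------------------------------------------
# Value types
# --------------------------------------------------------------------------

class ConceptRef(BaseModel):
    """A coded concept: vocabulary code, preferred term, semantic class."""

    code: str
    label: str = ""
    semantic_class: SemanticClass

    @field_validator("code")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        if not v:
            raise ValueError("concept code must be non-empty")
        return v


class CodedValue(BaseModel):
    kind: Literal["coded"] = "coded"
    code: str
    label: str = ""


class QuantityValue(BaseModel):
    kind: Literal["quantity"] = "quantity"
    value: float
    unit: str = ""


class TextValue(BaseModel):
    kind: Literal["text"] = "text"
    text: str


Value = Union[CodedValue, QuantityValue, TextValue]


class Period(BaseModel):
    """A calendar interval; ``None`` bounds are open-ended."""

    start: Optional[_dt.date] = None
    end: Optional[_dt.date] = None

    def overlaps(self, other: "Period") -> bool:
        a0 = self.start or _dt.date.min
        a1 = self.end or _dt.date.max
        b0 = other.start or _dt.date.min
        b1 = other.end or _dt.date.max
        return a0 < b1 and b0 < a1


# --------------------------------------------------------------------------
# Level 1 — mentions and documents
# --------------------------------------------------------------------------

class Mention(BaseModel):
    """A span-anchored coded annotation from one clinical document.

    Spans are 0-based half-open character offsets into the source text.
    """

    id: str
    document_id: str
    span: tuple[int, int]
    text: str = ""
    concept: ConceptRef
    polarity: Polarity = Polarity.affirmed
    uncertainty: Uncertainty = Uncertainty.certain
    doc_time_rel: DocTimeRel = DocTimeRel.OVERLAP
    value: Optional[Value] = Field(default=None, discriminator="kind")


class ClinicalDocument(BaseModel):
    """One dated clinical document with its ordered mentions."""

    id: str
    patient_id: str
    date: _dt.date
    doc_type: DocType = DocType.other
    mentions: list[Mention] = Field(default_factory=list)


# --------------------------------------------------------------------------
# Level 2 — event details and compositions
# --------------------------------------------------------------------------

class EventDetail(BaseModel):
    """A merged event typed by FHIR resource kind.

    One event detail summarizes all mentions of a document that share the
    merge key (concept code, polarity, resource kind). ``conflict_values``
    records distinct non-null values seen among contributors that could not
    be reconciled at Level 2; resolution is deferred to the rule engine.
    """

    id: str
    resource_kind: ResourceKind
    concept: ConceptRef
    polarity: Polarity
    uncertainty: Uncertainty = Uncertainty.certain
    value: Optional[Value] = Field(default=None, discriminator="kind")
    conflict_values: list[Value] = Field(default_factory=list)
    period: Optional[Period] = None
    #: assay-method qualifier (e.g. IHC, FISH) from the post-coordinated
    #: concept; drives rule precedence.
    method: Optional[str] = None
    document_id: str = ""
    doc_type: DocType = DocType.other
    #: document date, the event's coarse temporal anchor.
    date: Optional[_dt.date] = None
    #: True when every contributing mention is related BEFORE its document
    #: (an unbounded-before event that cannot anchor episode boundaries).
    before_document: bool = False


class Composition(BaseModel):
    """Per-document aggregation of merged event details (Level 2)."""

    document_id: str
    patient_id: str
    date: _dt.date
    doc_type: DocType = DocType.other
    event_details: list[EventDetail] = Field(default_factory=list)


# --------------------------------------------------------------------------
# Level 3 — episodes and the disease course
# --------------------------------------------------------------------------

class Episode(BaseModel):
    """A clinically meaningful interval typed by episode type and phase.

    Episodes are hierarchical (a whole-episode-type parent may contain its
    phase episodes as children; parents carry ``phase=None``) and may
    overlap other episodes. ``events`` holds event-detail ids; an event
    assigned to more than one episode is flagged in
    ``DiseaseCourse.multi_assigned``.
    """

    id: str
    episode_type: EpisodeType
    phase: Optional[Phase] = None
    start_date: _dt.date
    end_date: _dt.date
    start_event: Optional[str] = None
    end_event: Optional[str] = None
    child_episodes: list["Episode"] = Field(default_factory=list)
    events: list[str] = Field(default_factory=list)

    def walk(self) -> Iterable["Episode"]:
        """Yield this episode then all descendants, depth-first."""
        yield self
        for child in self.child_episodes:
            yield from child.walk()

    def leaves(self) -> Iterable["Episode"]:
        if not self.child_episodes:
            yield self
        else:
            for child in self.child_episodes:
                yield from child.leaves()


class DiseaseCourse(BaseModel):
    """The ordered timeline of a patient's episodes (Level 3)."""

    patient_id: str
    episodes: list[Episode] = Field(default_factory=list)
    #: event ids matching no episode are retained here, never dropped.
    unclassified: list[str] = Field(default_factory=list)
    #: event ids assigned to more than one episode.
    multi_assigned: list[str] = Field(default_factory=list)

    def all_episodes(self) -> Iterable[Episode]:
        for ep in self.episodes:
            yield from ep.walk()

    def leaf_episodes(self) -> Iterable[Episode]:
        for ep in self.episodes:
            yield from ep.leaves()


# --------------------------------------------------------------------------
# Level 4 — phenotypes
# --------------------------------------------------------------------------

class Assertion(BaseModel):
    """One rule-asserted attribute value with its audit trail."""

    id: str
    attribute: str
    value: Any = None
    rule_id: str = ""
    event_ids: list[str] = Field(default_factory=list)
    #: suppressed competing assertions (rule id, value) recorded for audit.
    conflicts: list[dict[str, Any]] = Field(default_factory=list)


class Manifestation(BaseModel):
    """A Clinical or Molecular manifestation of disease."""

    id: str = ""
    kind: ManifestationKind
    concept: ConceptRef
    value: Optional[Value] = Field(default=None, discriminator="kind")
    valid_period: Period = Field(default_factory=Period)


class TumorPhenotype(BaseModel):
    """Time-scoped attribute bundle for one tumor.

    A new phenotype record starts whenever any attribute changes value, so
    records of the same tumor have pairwise disjoint valid periods.
    """

    id: str = ""
    cancer_type: Optional[str] = None
    histologic_type: Optional[str] = None
    tumor_extent: Optional[str] = None
    manifestations: list[Manifestation] = Field(default_factory=list)
    valid_period: Period = Field(default_factory=Period)
    assertions: list[Assertion] = Field(default_factory=list)


class CancerPhenotype(BaseModel):
    """Time-scoped attribute bundle for the cancer as a whole."""

    id: str = ""
    cancer_type: Optional[str] = None
    histologic_type: Optional[str] = None
    tumor_extent: Optional[str] = None
    cancer_stage: Optional[str] = None
    t_classification: Optional[str] = None
    n_classification: Optional[str] = None
    m_classification: Optional[str] = None
    manifestations: list[Manifestation] = Field(default_factory=list)
    valid_period: Period = Field(default_factory=Period)
    assertions: list[Assertion] = Field(default_factory=list)


class Treatment(BaseModel):
    concept: ConceptRef
    period: Period = Field(default_factory=Period)
    intent: TreatmentIntent = TreatmentIntent.unknown
    id: str = ""

    @field_validator("period")
    @classmethod
    def _ordered(cls, v: Period) -> Period:
        if v.start and v.end and v.start > v.end:
            raise ValueError("treatment period start must precede end")
        return v


class Outcome(BaseModel):
    concept: ConceptRef
    period: Period = Field(default_factory=Period)
    id: str = ""


class SequenceVariation(BaseModel):
    """A germline or tumor sequence variation.

    Cross-referenced to the Sequence Ontology ``sequence_variant`` class
    (SO:0001060) via ``ontology_xref``.
    """

    id: str = ""
    scope: VariationScope
    gene: str
    description: str = ""
    ontology_xref: str = SEQUENCE_VARIANT_XREF


class Tumor(BaseModel):
    """An individual mass-occupying lesion and its phenotypes over time."""

    id: str
    episode_type: EpisodeType = EpisodeType.PrimaryTumor
    body_site: Optional[ConceptRef] = None
    phenotypes: list[TumorPhenotype] = Field(default_factory=list)
    treatments: list[Treatment] = Field(default_factory=list)


class Cancer(BaseModel):
    """The disease as a whole: its tumors, phenotypes, treatments, outcomes."""

    id: str
    tumors: list[Tumor] = Field(default_factory=list)
    phenotypes: list[CancerPhenotype] = Field(default_factory=list)
    treatments: list[Treatment] = Field(default_factory=list)
    outcomes: list[Outcome] = Field(default_factory=list)


class PatientSummary(BaseModel):
    """Level-4 summary attached to a patient record."""

    cancers: list[Cancer] = Field(default_factory=list)
    sequence_variations: list[SequenceVariation] = Field(default_factory=list)
    #: patient-level attributes (date_of_death, comorbidities, ...).
    patient_attributes: dict[str, Any] = Field(default_factory=dict)


# --------------------------------------------------------------------------
# Provenance
# --------------------------------------------------------------------------

class ProvenanceGraph:
    """Central store of ``wasDerivedFrom`` edges for one patient record.

    Edges point from the derived (higher-level) id to the source
    (lower-level) id. The graph is kept acyclic by construction: adding an
    edge that would close a derivation cycle raises :class:`CycleError`.
    """

    def __init__(self, edges: Iterable[tuple[str, str]] = ()) -> None:
        self._g = nx.DiGraph()
        for derived, source in edges:
            self.add_edge(derived, source)

    def add_edge(self, derived: str, source: str) -> None:
        if derived == source:
            raise CycleError(f"self-derivation of {derived!r}")
        if self._g.has_node(source) and self._g.has_node(derived) and \
                nx.has_path(self._g, source, derived):
            raise CycleError(f"edge {derived!r}->{source!r} closes a cycle")
        self._g.add_edge(derived, source)

    @property
    def edges(self) -> list[tuple[str, str]]:
        """All (derived, source) pairs in deterministic order."""
        return sorted(self._g.edges())

    def __len__(self) -> int:
        return self._g.number_of_edges()

    def __contains__(self, node: str) -> bool:
        return self._g.has_node(node)

    def sources_of(self, derived: str) -> list[str]:
        if not self._g.has_node(derived):
            return []
        return sorted(self._g.successors(derived))

    def closure(self, node: str) -> set[str]:
        """All ids transitively reachable from ``node`` via derivation."""
        if not self._g.has_node(node):
            raise NotFoundError(node)
        return set(nx.descendants(self._g, node))

    def path(self, from_id: str, to_id: str) -> Optional[list[tuple[str, str]]]:
        """One shortest derivation path as an edge list, or ``None``."""
        if not self._g.has_node(from_id) or not self._g.has_node(to_id):
            raise NotFoundError(from_id if not self._g.has_node(from_id) else to_id)
        try:
            nodes = nx.shortest_path(self._g, from_id, to_id)
        except nx.NetworkXNoPath:
            return None
        return list(zip(nodes[:-1], nodes[1:]))

    def to_list(self) -> list[list[str]]:
        return [list(e) for e in self.edges]

    def copy(self) -> "ProvenanceGraph":
        return ProvenanceGraph(self.edges)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ProvenanceGraph) and self.edges == other.edges


def derivation_closure(graph: ProvenanceGraph, node: str) -> set[str]:
    """All ids reachable from ``node`` via ``wasDerivedFrom`` edges.

    A Level-1 mention has no sources, so its closure is empty. An id absent
    from the graph entirely raises :class:`NotFoundError`, except mention
    ids, which are legitimate leaves even when no edge touches them.
    """
    if node not in graph:
        if node.startswith("men:"):
            return set()
        raise NotFoundError(node)
    return graph.closure(node)


def derivation_path(graph: ProvenanceGraph, from_id: str,
                    to_id: str) -> Optional[list[tuple[str, str]]]:
    """One shortest derivation path from ``from_id`` to ``to_id``, or None."""
    return graph.path(from_id, to_id)


# --------------------------------------------------------------------------
# The patient record container
# --------------------------------------------------------------------------

class PatientRecord:
    """A full multi-level patient record.

    Carries documents (Level 1) and, once the pipeline stages have run,
    compositions (Level 2), the disease course (Level 3), the phenotype
    summary (Level 4), and the central provenance graph linking them.
    """

    def __init__(self, patient_id: str,
                 documents: Optional[list[ClinicalDocument]] = None,
                 compositions: Optional[list[Composition]] = None,
                 course: Optional[DiseaseCourse] = None,
                 summary: Optional[PatientSummary] = None,
                 provenance: Optional[ProvenanceGraph] = None) -> None:
        self.patient_id = patient_id
        self.documents = documents or []
        self.compositions = compositions
        self.course = course
        self.summary = summary
        self.provenance = provenance or ProvenanceGraph()

    # -- lookups ----------------------------------------------------------

    def document_index(self) -> dict[str, ClinicalDocument]:
        return {d.id: d for d in self.documents}

    def mention_index(self) -> dict[str, Mention]:
        return {m.id: m for d in self.documents for m in d.mentions}

    def event_index(self) -> dict[str, EventDetail]:
        if not self.compositions:
            return {}
        return {e.id: e for c in self.compositions for e in c.event_details}

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return {
            "patient_id": self.patient_id,
            "documents": [d.model_dump(mode="json") for d in self.documents],
            "compositions": ([c.model_dump(mode="json") for c in self.compositions]
                             if self.compositions is not None else None),
            "course": self.course.model_dump(mode="json") if self.course else None,
            "summary": self.summary.model_dump(mode="json") if self.summary else None,
            "provenance": self.provenance.to_list(),
        }

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PatientRecord":
        return cls(
            patient_id=data["patient_id"],
            documents=[ClinicalDocument.model_validate(d)
                       for d in data.get("documents", [])],
            compositions=(None if data.get("compositions") is None else
                          [Composition.model_validate(c)
                           for c in data["compositions"]]),
            course=(DiseaseCourse.model_validate(data["course"])
                    if data.get("course") else None),
            summary=(PatientSummary.model_validate(data["summary"])
                     if data.get("summary") else None),
            provenance=ProvenanceGraph(
                tuple(e) for e in data.get("provenance", [])),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PatientRecord":
        return cls.from_dict(json.loads(text))

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "PatientRecord":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json(fh.read())

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, PatientRecord)
                and self.to_dict() == other.to_dict())


# --------------------------------------------------------------------------
# Record validation
# --------------------------------------------------------------------------

def _check_phenotype_periods(entity_id: str,
                             phenotypes: list, out: list[str]) -> None:
    # one value per attribute at a time: phenotype records of the same
    # entity must have pairwise non-overlapping valid periods.
    for i, a in enumerate(phenotypes):
        for b in phenotypes[i + 1:]:
            if a.valid_period.overlaps(b.valid_period):
                out.append(
                    f"{entity_id}: phenotype periods overlap "
                    f"({a.id!r} vs {b.id!r})")


def _check_attribute_values(entity_id: str, phen, lexicon: Lexicon,
                            out: list[str]) -> None:
    for attr in ("cancer_type", "histologic_type", "tumor_extent",
                 "cancer_stage"):
        val = getattr(phen, attr, None)
        if val is not None and not lexicon.value_allowed(attr, val):
            out.append(f"{entity_id}: {attr} value {val!r} outside value set")
    for attr in ("t_classification", "n_classification", "m_classification"):
        val = getattr(phen, attr, None)
        if val is not None and not lexicon.pattern_match(attr, val):
            out.append(f"{entity_id}: {attr} value {val!r} fails pattern")


def validate_record(record: PatientRecord,
                    lexicon: Optional[Lexicon] = None) -> list[str]:
    """Check every model invariant; return a list of violations.

    An empty list means the record is valid. Violations are data, not
    exceptions, and the record is never mutated.
    """
    lexicon = lexicon or default_lexicon()
    out: list[str] = []

    seen_mentions: set[str] = set()
    for doc in record.documents:
        prev_begin = -1
        for m in doc.mentions:
            if m.span[0] >= m.span[1]:
                out.append(f"{m.id}: span begin {m.span[0]} not before "
                           f"end {m.span[1]}")
            if m.document_id != doc.id:
                out.append(f"{m.id}: document_id {m.document_id!r} differs "
                           f"from containing document {doc.id!r}")
            if m.id in seen_mentions:
                out.append(f"{m.id}: duplicate mention id in record")
            seen_mentions.add(m.id)
            if m.span[0] < prev_begin:
                out.append(f"{doc.id}: mentions not sorted by span begin "
                           f"at {m.id}")
            prev_begin = m.span[0]

    if record.compositions is not None:
        docs = record.document_index()
        for comp in record.compositions:
            doc = docs.get(comp.document_id)
            if doc is None:
                out.append(f"composition for unknown document "
                           f"{comp.document_id!r}")
                continue
            doc_mentions = {m.id for m in doc.mentions}
            covered: set[str] = set()
            for ev in comp.event_details:
                srcs = set(record.provenance.sources_of(ev.id))
                men_srcs = {s for s in srcs if s.startswith("men:")}
                if not men_srcs:
                    out.append(f"{ev.id}: event detail has no provenance "
                               f"edge to a mention")
                if covered & men_srcs:
                    out.append(f"{ev.id}: derived-from mentions overlap "
                               f"another event detail")
                covered |= men_srcs
            if covered != doc_mentions:
                out.append(f"{comp.document_id}: event details do not "
                           f"partition the document's mentions")

    if record.course is not None:
        for ep in record.course.all_episodes():
            if ep.start_date > ep.end_date:
                out.append(f"{ep.id}: start_date after end_date")
            if not ep.events:
                out.append(f"{ep.id}: episode has no events")
            for child in ep.child_episodes:
                if (child.start_date < ep.start_date
                        or child.end_date > ep.end_date):
                    out.append(f"{child.id}: child episode extends outside "
                               f"parent {ep.id}")
        starts = [ep.start_date for ep in record.course.episodes]
        if starts != sorted(starts):
            out.append("disease course episodes not ordered by start_date")

    if record.summary is not None:
        tumor_ids: list[str] = []
        for cancer in record.summary.cancers:
            for tumor in cancer.tumors:
                tumor_ids.append(tumor.id)
                _check_phenotype_periods(tumor.id, tumor.phenotypes, out)
                for phen in tumor.phenotypes:
                    _check_attribute_values(tumor.id, phen, lexicon, out)
            _check_phenotype_periods(cancer.id, cancer.phenotypes, out)
            for phen in cancer.phenotypes:
                _check_attribute_values(cancer.id, phen, lexicon, out)
            for trt in cancer.treatments + [t for tu in cancer.tumors
                                            for t in tu.treatments]:
                if (trt.period.start and trt.period.end
                        and trt.period.start > trt.period.end):
                    out.append(f"{trt.id}: treatment period start after end")
        if len(tumor_ids) != len(set(tumor_ids)):
            out.append("a tumor belongs to more than one cancer")

        # provenance completeness: every Level-4 assertion reaches a mention
        for cancer in record.summary.cancers:
            level4: list[str] = []
            for phen in cancer.phenotypes:
                level4 += [a.id for a in phen.assertions]
            for tumor in cancer.tumors:
                for phen in tumor.phenotypes:
                    level4 += [a.id for a in phen.assertions]
            level4 += [t.id for t in cancer.treatments if t.id]
            for node in level4:
                try:
                    closure = derivation_closure(record.provenance, node)
                except NotFoundError:
                    out.append(f"{node}: absent from provenance graph")
                    continue
                if not any(n.startswith("men:") for n in closure):
                    out.append(f"{node}: derivation closure reaches no "
                               f"mention")

    if not nx.is_directed_acyclic_graph(record.provenance._g):
        out.append("provenance graph is cyclic")

    return out
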