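"""Aggregating document mentions into merged event details (Level 1 → 2).

Mentions of one document that share the merge key — (concept code,
polarity, resource kind) — collapse into a single event detail, so three
affirmed mentions of a Mass in one note become one event carrying three
``wasDerivedFrom`` edges. Negated and affirmed mentions of the same concept
never merge. Merging is deterministic and independent of mention input
order.

Value reconciliation within a merge group keeps the most specific non-null
value (structured coded/quantity values outrank free text); distinct
unreconciled values are retained as a conflict annotation on the event
detail rather than silently discarded, because downstream abstraction rules
(e.g. FISH-over-IHC precedence) may need that evidence.
"""

from __future__ import annotations

from typing import Optional

from .lexicon import Lexicon, default_lexicon
from .model import (ClinicalDocument, Composition, DocTimeRel, EventDetail,
                    Mention, PatientRecord, Polarity, ProvenanceGraph,
                    ResourceKind, SemanticClass, Uncertainty, Value)

__all__ = ["map_resource_kind", "build_composition", "compose_record"]

_KIND_MAP = {
    SemanticClass.Condition: ResourceKind.Condition,
    SemanticClass.Procedure: ResourceKind.Procedure,
    SemanticClass.Medication: ResourceKind.MedicationStatement,
    SemanticClass.Observation: ResourceKind.Observation,
    SemanticClass.AnatomicalSite: ResourceKind.BodySite,
}


def map_resource_kind(mention: Mention) -> ResourceKind:
    """Map a mention's semantic class onto its FHIR resource kind.

    The mapping is total on the semantic-class enum and covers five of the
    six resource kinds; Patient resources are populated from document
    metadata, not from mentions.
    """
    return _KIND_MAP[mention.concept.semantic_class]


def _value_rank(v: Optional[Value]) -> int:
    if v is None:
        return 0
    return 1 if v.kind == "text" else 2


def build_composition(document: ClinicalDocument,
                      lexicon: Optional[Lexicon] = None,
                      ) -> tuple[Composition, list[tuple[str, str]]]:
    """Build one composition and its provenance edges from a document.

    Returns the composition together with ``(event_id, mention_id)``
    derivation edges; every mention of the document contributes to exactly
    one event detail (the partition property).
    """
    lexicon = lexicon or default_lexicon()
    groups: dict[tuple[str, str, str], list[Mention]] = {}
    for m in sorted(document.mentions, key=lambda m: (m.span[0], m.span[1], m.id)):
        key = (m.concept.code, m.polarity.value, map_resource_kind(m).value)
        groups.setdefault(key, []).append(m)

    events: list[EventDetail] = []
    edges: list[tuple[str, str]] = []
    for n, key in enumerate(sorted(groups), start=1):
        code, polarity, kind = key
        members = groups[key]
        values: list[Value] = []
        for m in members:
            if m.value is not None and m.value not in values:
                values.append(m.value)
        best = max((_value_rank(v) for v in values), default=0)
        primary = next((v for v in values if _value_rank(v) == best), None)
        conflicts = [v for v in values
                     if v != primary and _value_rank(v) == best]
        concept_entry = lexicon.get(code)
        event = EventDetail(
            id=f"evt:{document.id}:{n}",
            resource_kind=ResourceKind(kind),
            concept=members[0].concept,
            polarity=Polarity(polarity),
            uncertainty=(Uncertainty.uncertain
                         if any(m.uncertainty is Uncertainty.uncertain
                                for m in members)
                         else Uncertainty.certain),
            value=primary,
            conflict_values=conflicts,
            method=concept_entry.method if concept_entry else None,
            document_id=document.id,
            doc_type=document.doc_type,
            date=document.date,
            before_document=all(m.doc_time_rel is DocTimeRel.BEFORE
                                for m in members),
        )
        events.append(event)
        edges.extend((event.id, m.id) for m in members)

    comp = Composition(document_id=document.id, patient_id=document.patient_id,
                       date=document.date, doc_type=document.doc_type,
                       event_details=events)
    return comp, edges


def compose_record(record: PatientRecord,
                   lexicon: Optional[Lexicon] = None) -> PatientRecord:
    """Build one composition per document, in place, recording provenance."""
    compositions = []
    for doc in record.documents:
        comp, edges = build_composition(doc, lexicon)
        compositions.append(comp)
        for derived, source in edges:
            record.provenance.add_edge(derived, source)
    record.compositions = compositions
    return record
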