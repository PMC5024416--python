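"""Interoperable serializations of summarized records.

Two formats are supported:

* **FHIR DSTU2-style JSON** — event details are emitted as their mapped
  resources (Condition, Observation, BodySite, Procedure,
  MedicationStatement) inside one collection Bundle, with a Composition
  per document sectioned by resource kind, episodes as extensions of the
  Bundle resource, Level-4 entities as Condition/Observation/Basic
  resources, and one Provenance resource per derived entity. Resource ids
  are derived stably from internal ids (``:`` becomes ``.``). Alongside
  the native fields, every exported object carries a ``source`` extension
  holding its canonical JSON, which makes the export losslessly
  re-importable without forcing every model nuance through DSTU2 fields.

* **RDF** — one ``prov:wasDerivedFrom`` triple per provenance edge, typed
  nodes for every entity, and Sequence Ontology cross-references
  (SO:0001060) on sequence-variation nodes via ``rdfs:seeAlso``. The
  canonical on-disk form is sorted N-Triples, which is deterministic
  across runs; a Turtle rendering is offered for readability.
"""

from __future__ import annotations

import json
from typing import Any, Optional

from rdflib import Graph, Literal, Namespace, RDF, RDFS, URIRef

from .model import (Cancer, ClinicalDocument, Composition, DiseaseCourse,
                    Episode, EventDetail, Mention, PatientRecord,
                    PatientSummary, ProvenanceGraph, SequenceVariation,
                    Treatment, Tumor)

__all__ = ["ExportError", "export_fhir_json", "import_fhir_json",
           "export_rdf", "rdf_to_canonical_nt", "rdf_to_turtle",
           "ONCOPHEN", "PROV", "SO_SEQUENCE_VARIANT"]


class ExportError(ValueError):
    """Raised when a record is not ready for export."""


EXT = "urn:oncophen:ext:"
NCIT_SYSTEM = "urn:oncophen:ncit"

PROV = Namespace("http://www.w3.org/ns/prov#")
ONCOPHEN = Namespace("urn:oncophen:model#")
SO_SEQUENCE_VARIANT = URIRef("http://purl.obolibrary.org/obo/SO_0001060")


def _fid(internal_id: str) -> str:
    """Internal id -> FHIR-safe resource id (stable, reversible)."""
    return internal_id.replace(":", ".")


def _iid(fhir_id: str) -> str:
    return fhir_id.replace(".", ":")


def _ext(url_suffix: str, **value: Any) -> dict[str, Any]:
    return {"url": EXT + url_suffix, **value}


def _source_ext(obj) -> dict[str, Any]:
    payload = obj.model_dump(mode="json")
    return _ext("source", valueString=json.dumps(payload, sort_keys=True))


def _coding(concept) -> dict[str, Any]:
    return {"coding": [{"system": NCIT_SYSTEM, "code": concept.code,
                        "display": concept.label}]}


def _subject(pid: str) -> dict[str, str]:
    return {"reference": f"Patient/{_fid(pid)}"}


# --------------------------------------------------------------------------
# FHIR export
# --------------------------------------------------------------------------

def _mention_resource(m: Mention, pid: str) -> dict[str, Any]:
    return {
        "resourceType": "Basic",
        "id": _fid(m.id),
        "code": {**_coding(m.concept), "text": m.text},
        "subject": _subject(pid),
        "extension": [
            _ext("document", valueString=m.document_id),
            _ext("spanBegin", valueInteger=m.span[0]),
            _ext("spanEnd", valueInteger=m.span[1]),
            _ext("polarity", valueString=m.polarity.value),
            _ext("docTimeRel", valueString=m.doc_time_rel.value),
            _source_ext(m),
        ],
    }


def _event_resource(e: EventDetail, pid: str) -> dict[str, Any]:
    kind = e.resource_kind.value
    res: dict[str, Any] = {"resourceType": kind, "id": _fid(e.id)}
    if kind == "MedicationStatement":
        res["medicationCodeableConcept"] = _coding(e.concept)
        res["patient"] = _subject(pid)
    elif kind == "BodySite":
        res["code"] = _coding(e.concept)
        res["patient"] = _subject(pid)
    else:
        res["code"] = _coding(e.concept)
        res["subject"] = _subject(pid)
    if kind == "Observation" and e.value is not None:
        if e.value.kind == "coded":
            res["valueCodeableConcept"] = {
                "coding": [{"system": NCIT_SYSTEM, "code": e.value.code}]}
        elif e.value.kind == "quantity":
            res["valueQuantity"] = {"value": e.value.value,
                                    "unit": e.value.unit}
        else:
            res["valueString"] = e.value.text
    res["extension"] = [
        _ext("polarity", valueString=e.polarity.value),
        _ext("documentId", valueString=e.document_id),
        _ext("docType", valueString=e.doc_type.value),
        _source_ext(e),
    ]
    if e.method:
        res["extension"].insert(0, _ext("method", valueString=e.method))
    return res


def _composition_resource(c: Composition) -> dict[str, Any]:
    sections = []
    by_kind: dict[str, list[EventDetail]] = {}
    for e in c.event_details:
        by_kind.setdefault(e.resource_kind.value, []).append(e)
    for kind in sorted(by_kind):
        sections.append({
            "title": kind,
            "entry": [{"reference": f"{kind}/{_fid(e.id)}"}
                      for e in by_kind[kind]],
        })
    return {
        "resourceType": "Composition",
        "id": _fid(c.document_id),
        "date": c.date.isoformat(),
        "type": {"text": c.doc_type.value},
        "subject": _subject(c.patient_id),
        "title": f"composition of {c.document_id}",
        "section": sections,
        "extension": [_source_ext(c)],
    }


def _episode_resource(ep: Episode) -> dict[str, Any]:
    ext = [
        _ext("episodeType", valueString=ep.episode_type.value),
        _ext("startDate", valueDate=ep.start_date.isoformat()),
        _ext("endDate", valueDate=ep.end_date.isoformat()),
        _source_ext(ep),
    ]
    if ep.phase is not None:
        ext.insert(1, _ext("phase", valueString=ep.phase.value))
    return {
        # episodes extend the FHIR Bundle resource
        "resourceType": "Bundle",
        "type": "collection",
        "id": _fid(ep.id),
        "extension": ext,
    }


def _summary_resources(summary: PatientSummary, pid: str) -> list[dict]:
    resources: list[dict] = []
    for cancer in summary.cancers:
        resources.append({
            "resourceType": "Condition",
            "id": _fid(cancer.id),
            "subject": _subject(pid),
            "code": {"text": "cancer (disease-level summary)"},
            "extension": [
                _ext("level4Kind", valueString="cancer"),
                _source_ext(cancer),
            ],
        })
        for tumor in cancer.tumors:
            res = {
                "resourceType": "Condition",
                "id": _fid(tumor.id),
                "subject": _subject(pid),
                "code": {"text": f"tumor ({tumor.episode_type.value})"},
                "extension": [
                    _ext("level4Kind", valueString="tumor"),
                    _source_ext(tumor),
                ],
            }
            if tumor.body_site is not None:
                res["bodySite"] = [_coding(tumor.body_site)]
            resources.append(res)
        for trt in cancer.treatments:
            resources.append({
                "resourceType": "Basic",
                "id": _fid(trt.id),
                "subject": _subject(pid),
                "code": _coding(trt.concept),
                "extension": [
                    _ext("level4Kind", valueString="treatment"),
                    _ext("intent", valueString=trt.intent.value),
                    _source_ext(trt),
                ],
            })
        for out in cancer.outcomes:
            resources.append({
                "resourceType": "Basic",
                "id": _fid(out.id),
                "subject": _subject(pid),
                "code": _coding(out.concept),
                "extension": [
                    _ext("level4Kind", valueString="outcome"),
                    _source_ext(out),
                ],
            })
    for var in summary.sequence_variations:
        resources.append({
            "resourceType": "Basic",
            "id": _fid(var.id),
            "subject": _subject(pid),
            "code": {"text": f"{var.scope.value} sequence variation "
                             f"({var.gene})"},
            "extension": [
                _ext("level4Kind", valueString="sequenceVariation"),
                _ext("seeAlso", valueString=var.ontology_xref),
                _source_ext(var),
            ],
        })
    return resources


def export_fhir_json(record: PatientRecord) -> dict[str, Any]:
    """Export a summarized record as one FHIR DSTU2-style collection Bundle.

    Raises :class:`ExportError` on an unsummarized record, pointing to the
    summarize step.
    """
    if record.summary is None or record.compositions is None \
            or record.course is None:
        raise ExportError("record is not summarized; run the pipeline "
                          "(compose, segment, summarize) before exporting")
    pid = record.patient_id
    entries: list[dict[str, Any]] = []

    patient_res: dict[str, Any] = {"resourceType": "Patient", "id": _fid(pid)}
    if record.summary.patient_attributes:
        patient_res["extension"] = [
            _ext("patientAttributes", valueString=json.dumps(
                record.summary.patient_attributes, sort_keys=True))]
    entries.append(patient_res)

    for doc in record.documents:
        for m in doc.mentions:
            entries.append(_mention_resource(m, pid))
    for comp in record.compositions:
        for e in comp.event_details:
            entries.append(_event_resource(e, pid))
        entries.append(_composition_resource(comp))
    for ep in record.course.all_episodes():
        entries.append(_episode_resource(ep))
    entries.append({
        "resourceType": "Basic",
        "id": _fid(f"course:{pid}"),
        "code": {"text": "disease course"},
        "extension": [_source_ext(record.course)],
    })
    entries.extend(_summary_resources(record.summary, pid))

    for derived in sorted({d for d, _ in record.provenance.edges}):
        entries.append({
            "resourceType": "Provenance",
            "id": _fid(f"prov:{derived}"),
            "target": [{"reference": _fid(derived)}],
            "entity": [{"role": "source", "reference": _fid(s)}
                       for s in record.provenance.sources_of(derived)],
        })

    return {
        "resourceType": "Bundle",
        "type": "collection",
        "id": _fid(f"bundle:{pid}"),
        "entry": [{"resource": r} for r in entries],
    }


# --------------------------------------------------------------------------
# FHIR import
# --------------------------------------------------------------------------

def _get_source(resource: dict[str, Any]) -> Optional[dict[str, Any]]:
    for ext in resource.get("extension", []):
        if ext.get("url") == EXT + "source":
            return json.loads(ext["valueString"])
    return None


def import_fhir_json(bundle: dict[str, Any]) -> PatientRecord:
    """Reconstruct a patient record from an exported bundle."""
    if bundle.get("resourceType") != "Bundle":
        raise ExportError("not a Bundle document")
    resources = [e["resource"] for e in bundle.get("entry", [])]
    patient = next((r for r in resources
                    if r["resourceType"] == "Patient"), None)
    if patient is None:
        raise ExportError("bundle contains no Patient resource")
    pid = _iid(patient["id"])

    mentions: dict[str, list[Mention]] = {}
    compositions: list[Composition] = []
    course: Optional[DiseaseCourse] = None
    summary = PatientSummary()
    edges: list[tuple[str, str]] = []

    for res in resources:
        rtype = res["resourceType"]
        src = _get_source(res)
        if rtype == "Basic" and src is not None and "span" in src:
            m = Mention.model_validate(src)
            mentions.setdefault(m.document_id, []).append(m)
        elif rtype == "Composition" and src is not None:
            compositions.append(Composition.model_validate(src))
        elif rtype == "Basic" and res["id"].startswith("course."):
            course = DiseaseCourse.model_validate(src)
        elif rtype == "Condition" and src is not None:
            kind = next((e["valueString"] for e in res.get("extension", [])
                         if e["url"] == EXT + "level4Kind"), None)
            if kind == "cancer":
                summary.cancers.append(Cancer.model_validate(src))
            # tumors/treatments/outcomes ride inside the cancer source
        elif rtype == "Basic" and src is not None and "scope" in src:
            summary.sequence_variations.append(
                SequenceVariation.model_validate(src))
        elif rtype == "Provenance":
            target = _iid(res["target"][0]["reference"])
            for ent in res.get("entity", []):
                edges.append((target, _iid(ent["reference"])))

    for ext in patient.get("extension", []):
        if ext["url"] == EXT + "patientAttributes":
            summary.patient_attributes = json.loads(ext["valueString"])

    documents = []
    for comp in compositions:
        doc_mentions = sorted(mentions.get(comp.document_id, []),
                              key=lambda m: (m.span[0], m.span[1], m.id))
        documents.append(ClinicalDocument(
            id=comp.document_id, patient_id=comp.patient_id, date=comp.date,
            doc_type=comp.doc_type, mentions=doc_mentions))

    has_summary = bool(summary.cancers or summary.sequence_variations
                       or summary.patient_attributes)
    return PatientRecord(
        patient_id=pid, documents=documents, compositions=compositions,
        course=course, summary=summary if has_summary else PatientSummary(),
        provenance=ProvenanceGraph(edges))


# --------------------------------------------------------------------------
# RDF export
# --------------------------------------------------------------------------

_PREFIX_CLASSES = {
    "men": ONCOPHEN.Mention, "doc": ONCOPHEN.Document,
    "evt": ONCOPHEN.EventDetail, "epi": ONCOPHEN.Episode,
    "tum": ONCOPHEN.Tumor, "can": ONCOPHEN.Cancer,
    "trt": ONCOPHEN.Treatment, "out": ONCOPHEN.Outcome,
    "var": ONCOPHEN.SequenceVariation,
}


def _node_class(node_id: str):
    if node_id.startswith("phe:p:"):
        return ONCOPHEN.Phenotype
    if node_id.startswith("phe:a:"):
        return ONCOPHEN.Assertion
    prefix = node_id.split(":", 1)[0]
    return _PREFIX_CLASSES.get(prefix, ONCOPHEN.Entity)


def _uri(node_id: str) -> URIRef:
    return URIRef("urn:oncophen:" + node_id)


def export_rdf(record: PatientRecord) -> Graph:
    """Export a record's derivation graph and entities as RDF.

    One ``prov:wasDerivedFrom`` triple per provenance edge; one
    ``rdf:type`` triple per entity appearing in the graph (or declared in
    the summary); sequence-variation nodes additionally carry the
    SO:0001060 cross-reference via ``rdfs:seeAlso`` plus their gene symbol
    and scope. An empty record yields an empty graph.
    """
    g = Graph()
    g.bind("prov", PROV)
    g.bind("op", ONCOPHEN)
    nodes: set[str] = set()
    for derived, source in record.provenance.edges:
        g.add((_uri(derived), PROV.wasDerivedFrom, _uri(source)))
        nodes.add(derived)
        nodes.add(source)
    variations: list[SequenceVariation] = (
        record.summary.sequence_variations if record.summary else [])
    nodes.update(v.id for v in variations)
    for node in sorted(nodes):
        g.add((_uri(node), RDF.type, _node_class(node)))
    for var in variations:
        g.add((_uri(var.id), RDFS.seeAlso, SO_SEQUENCE_VARIANT))
        g.add((_uri(var.id), ONCOPHEN.gene, Literal(var.gene)))
        g.add((_uri(var.id), ONCOPHEN.scope, Literal(var.scope.value)))
    return g


def rdf_to_canonical_nt(graph: Graph) -> str:
    """Deterministic serialization: sorted N-Triples, one per line."""
    lines = sorted(
        line for line in graph.serialize(format="nt").splitlines() if line)
    return "\n".join(lines) + ("\n" if lines else "")


def rdf_to_turtle(graph: Graph) -> str:
    """Turtle rendering (readable; triple order not guaranteed stable)."""
    return graph.serialize(format="turtle")
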