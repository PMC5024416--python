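"""Reading and validating mention-level annotation files (Level 1).

The interchange is one UTF-8 JSON file per clinical document: document
metadata (id, patient id, ISO-8601 date, document type) plus an array of
span-anchored mentions shaped like concept-recognition output from a
clinical NLP engine. The published JSON Schema for the format lives at
``oncophen/data/mention_file.schema.json`` and is generated from the same
pydantic model that performs validation here, so the two cannot drift.

Rejection is total: a file or patient bundle that fails validation raises
before any partially-loaded record escapes.
"""

from __future__ import annotations

import datetime as _dt
import json
from typing import Any, Iterable, Optional

from pydantic import BaseModel, Field, ValidationError

from .model import (ClinicalDocument, DocType, Mention, PatientRecord)

__all__ = [
    "IngestError", "MentionFileParseError", "MentionFileValidationError",
    "PatientConflictError", "MentionFile", "mention_file_schema",
    "read_mention_file", "write_mention_file", "document_to_mention_file",
    "assemble_patient",
]


class IngestError(ValueError):
    """Base class for ingest failures."""


class MentionFileParseError(IngestError):
    """Malformed JSON; carries line/column context from the parser."""


class MentionFileValidationError(IngestError):
    """Schema violation; lists the failing fields."""

    def __init__(self, path: str, errors: list[str]) -> None:
        self.errors = errors
        super().__init__(
            f"{path}: {len(errors)} schema violation(s): " + "; ".join(errors))


class PatientConflictError(IngestError):
    """Mixed patient ids or duplicate document ids in one bundle."""


class _DocumentMeta(BaseModel):
    id: str
    patient_id: str
    date: _dt.date
    doc_type: DocType = DocType.other


class MentionFile(BaseModel):
    """The mention-file interchange format (one clinical document)."""

    format: str = Field(default="oncophen-mentions-1", frozen=True)
    document: _DocumentMeta
    mentions: list[Mention] = Field(default_factory=list)


def mention_file_schema() -> dict[str, Any]:
    """The JSON Schema of the mention-file interchange format."""
    return MentionFile.model_json_schema()


def _to_document(mf: MentionFile, path: str) -> ClinicalDocument:
    errors: list[str] = []
    mentions = []
    for m in mf.mentions:
        if m.document_id and m.document_id != mf.document.id:
            errors.append(f"mentions[{m.id}].document_id != document.id")
        mentions.append(m.model_copy(update={"document_id": mf.document.id}))
    if errors:
        raise MentionFileValidationError(path, errors)
    mentions.sort(key=lambda m: (m.span[0], m.span[1], m.id))
    doc = ClinicalDocument(id=mf.document.id, patient_id=mf.document.patient_id,
                           date=mf.document.date, doc_type=mf.document.doc_type,
                           mentions=mentions)
    bad_spans = [m.id for m in mentions if m.span[0] >= m.span[1]]
    if bad_spans:
        raise MentionFileValidationError(
            path, [f"mentions[{i}].span: begin must be < end" for i in bad_spans])
    ids = [m.id for m in mentions]
    if len(ids) != len(set(ids)):
        raise MentionFileValidationError(path, ["duplicate mention ids"])
    return doc


def read_mention_file(path) -> ClinicalDocument:
    """Read and validate one mention file into a :class:`ClinicalDocument`.

    Mentions come back sorted by span begin. Malformed JSON raises
    :class:`MentionFileParseError` with line context; schema violations
    raise :class:`MentionFileValidationError` listing the failing fields.
    """
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise MentionFileParseError(
            f"{path}: invalid JSON at line {exc.lineno} column {exc.colno}: "
            f"{exc.msg}") from exc
    try:
        mf = MentionFile.model_validate(data)
    except ValidationError as exc:
        fields = [".".join(str(p) for p in err["loc"]) + ": " + err["msg"]
                  for err in exc.errors()]
        raise MentionFileValidationError(str(path), fields) from exc
    return _to_document(mf, str(path))


def document_to_mention_file(doc: ClinicalDocument) -> dict[str, Any]:
    """Render a document in the canonical mention-file JSON shape."""
    mf = MentionFile(
        document=_DocumentMeta(id=doc.id, patient_id=doc.patient_id,
                               date=doc.date, doc_type=doc.doc_type),
        mentions=sorted(doc.mentions, key=lambda m: (m.span[0], m.span[1], m.id)),
    )
    return mf.model_dump(mode="json", exclude_none=True)


def write_mention_file(doc: ClinicalDocument, path) -> None:
    """Write a document as a canonical (sorted-key) mention file."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(document_to_mention_file(doc), fh, sort_keys=True, indent=2)
        fh.write("\n")


def assemble_patient(paths: Iterable) -> PatientRecord:
    """Bundle mention files into one patient record (documents only).

    All files must share a patient id; duplicate document ids are rejected.
    Documents are ordered by date then id, independent of input order.
    """
    documents = [read_mention_file(p) for p in paths]
    if not documents:
        raise PatientConflictError("no mention files given")
    patient_ids = sorted({d.patient_id for d in documents})
    if len(patient_ids) > 1:
        raise PatientConflictError(
            f"mixed patient ids in one bundle: {patient_ids}")
    doc_ids = [d.id for d in documents]
    dups = sorted({i for i in doc_ids if doc_ids.count(i) > 1})
    if dups:
        raise PatientConflictError(f"duplicate document ids: {dups}")
    documents.sort(key=lambda d: (d.date, d.id))
    return PatientRecord(patient_id=patient_ids[0], documents=documents)
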