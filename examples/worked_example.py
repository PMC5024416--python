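"""Four-document breast-cancer record, end to end.

Builds the canonical worked example — a diagnostic workup (mammogram and
mass, needle biopsy, invasive ductal carcinoma with T1 N0 M0 and a BRCA
test) followed months later by metastatic imaging (MRI, enhancing lesion,
metastatic carcinoma) — and runs the full pipeline: compositions, episode
segmentation, and the phenotype summary with provenance.
"""

import datetime as dt

from oncophen import run_pipeline, derivation_path
from oncophen.episodes import episode_timeline
from oncophen.lexicon import default_lexicon
from oncophen.model import (ClinicalDocument, CodedValue, ConceptRef,
                            DocType, Mention, PatientRecord)


def document(doc_id, date, doc_type, codes, pid="pt1"):
    lexicon = default_lexicon()
    mentions = []
    for n, item in enumerate(codes, start=1):
        code, value = item if isinstance(item, tuple) else (item, None)
        concept = lexicon[code]
        begin = 40 * n
        mentions.append(Mention(
            id=f"men:{pid}:{doc_id}:{n}", document_id=doc_id,
            span=(begin, begin + len(concept.label)), text=concept.label,
            concept=ConceptRef(code=concept.code, label=concept.label,
                               semantic_class=concept.semantic_class),
            value=value))
    return ClinicalDocument(id=doc_id, patient_id=pid, date=date,
                            doc_type=doc_type, mentions=mentions)


d = dt.date
record = PatientRecord(patient_id="pt1", documents=[
    document("d1", d(2011, 3, 1), DocType.radiology, ["C16818", "C25315"]),
    document("d2", d(2011, 3, 10), DocType.pathology, ["C15361", "C25315"]),
    document("d3", d(2011, 3, 20), DocType.pathology,
             ["C4194", ("C48885", CodedValue(code="T1")),
              ("C48884", CodedValue(code="N0")),
              ("C48883", CodedValue(code="M0")),
              ("C900220", CodedValue(code="negative"))]),
    document("d4", d(2011, 9, 5), DocType.radiology,
             ["C16809", "C120180", "C36263"]),
])
run_pipeline(record)

print("Disease-course timeline:")
for ep, start, end in episode_timeline(record.course):
    print(f"  {ep.episode_type.value}/{ep.phase.value}: {start} .. {end} "
          f"({len(ep.events)} events)")

(cancer,) = record.summary.cancers
print(f"\nOne cancer with {len(cancer.tumors)} tumors:")
for tumor in cancer.tumors:
    site = tumor.body_site.label if tumor.body_site else "unknown site"
    print(f"  {tumor.episode_type.value} tumor in the {site}")

phen = cancer.phenotypes[-1]
print(f"\nCancer phenotype: {phen.cancer_type}, {phen.histologic_type}, "
      f"{phen.tumor_extent}, {phen.t_classification} "
      f"{phen.n_classification} {phen.m_classification}")

# every asserted value traces back to the mentions that support it
assertion = phen.assertions[0]
path = derivation_path(record.provenance, assertion.id,
                       assertion.event_ids[0])
print(f"\nDerivation path of '{assertion.attribute}':")
for derived, source in path:
    print(f"  {derived}  wasDerivedFrom  {source}")

# Expected: a PrimaryTumor/Diagnostic episode over documents 1-3, a
# MetastaticTumor/Diagnostic episode over document 4, and a summary whose
# single cancer holds one primary and one metastatic tumor, with each
# phenotype attribute linked to its source events.
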