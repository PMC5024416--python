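# oncophen

Multi-level computable cancer phenotypes from clinical-NLP annotations.

Key phenotypic variables in cancer — histology, receptor status, extent of
disease, response to treatment — live in free-text clinical notes, and
turning them into computable, longitudinal patient descriptions is still
largely manual. `oncophen` is an executable reference implementation of a
four-level cancer-phenotype information model for clinical informaticians
and translational researchers who need that abstraction pipeline to be
inspectable and testable end to end:

1. **Mentions** — span-anchored coded annotations (NCI-Thesaurus-style
   concepts, polarity, uncertainty, document-time relation), read from a
   published JSON interchange format shaped like clinical-NLP output;
2. **Compositions** — per-document summaries in which mentions sharing
   *(concept, polarity, resource kind)* merge into event details typed by
   a six-resource FHIR DSTU2 subset (Condition, Patient, Observation,
   BodySite, Procedure, MedicationStatement);
3. **Episodes** — clinically meaningful intervals (episode type × phase,
   e.g. *Primary Tumor / Diagnostic*), hierarchical and possibly
   overlapping, ordered into a disease-course timeline by declarative
   boundary triggers;
4. **Phenotypes** — time-scoped attribute bundles (cancer type, histologic
   type, tumor extent, stage, TNM, clinical and molecular manifestations)
   asserted on Cancer and Tumor entities by prioritized declarative rules
   — including assay-method precedence, where a FISH result outranks a
   discordant IHC result.

Every assertion above Level 1 is linked to its sources through a central
`prov:wasDerivedFrom` graph, so the transitive closure of any summarized
value reaches the exact mentions that support it. Summarized cohorts are
queryable through five competency-question operations (criteria, event
interval, stratification, triangulation, schema availability), and records
export as FHIR DSTU2-style JSON bundles or RDF with PROV derivation
triples. A seeded synthetic-record generator with ground truth makes the
whole pipeline testable without clinical data.

## Worked example

`examples/worked_example.py` builds a four-document record — mammogram and
mass, needle biopsy, a pathology panel (invasive ductal carcinoma, T1 N0
M0, BRCA test), then metastatic imaging six months later — and runs the
pipeline:

```
Disease-course timeline:
  PrimaryTumor/Diagnostic: 2011-03-01 .. 2011-03-20 (9 events)
  MetastaticTumor/Diagnostic: 2011-09-05 .. 2011-09-05 (3 events)

One cancer with 2 tumors:
  MetastaticTumor tumor in the unknown site
  PrimaryTumor tumor in the Breast

Cancer phenotype: carcinoma, ductal, invasive, T1 N0 M0

Derivation path of 'cancer_type':
  phe:a:can:pt1:1:1  wasDerivedFrom  evt:d3:1
```

The workup documents form the primary diagnostic episode, the imaging
document a metastatic one; both tumors attach to a single cancer, and the
asserted cancer type traces through the diagnosis event back to its
mentions. The other examples demonstrate FISH-over-IHC precedence
(`assay_precedence.py`), the five cohort queries (`cohort_queries.py`),
and the FHIR/RDF exports (`export_formats.py`). The same functionality is
scriptable via the `oncophen` CLI (`simulate`, `ingest`, `compose`,
`episodes`, `summarize`, `query`, `export`).

## Layout

- `src/oncophen/` — the library: `model` (types, provenance), `lexicon`,
  `ingest`, `compose`, `episodes`, `rules`, `query`, `simulate`,
  `export`, `cli`;
- `src/oncophen/data/` — bundled concept lexicon, episode configuration,
  breast-cancer ruleset, and the mention-file JSON Schema;
- `docs/methods.md` — the model, its assumptions, defaults, and limits;
- `examples/` — one narrative script per capability;
- `tests/` — the pytest suite, including end-to-end acceptance checks.
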