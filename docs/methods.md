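# Methods

## The model

`oncophen` represents a patient's cancer record at four levels of
abstraction and keeps the levels connected by provenance.

**Level 1 — mentions.** The input is one JSON file per clinical document:
document metadata (id, patient id, ISO-8601 date, document type) plus
span-anchored mentions, each carrying a coded concept (NCI-Thesaurus-style
`C`-code, preferred term, semantic class), polarity
(affirmed/negated), uncertainty, a document-time relation (BEFORE,
OVERLAP, AFTER, BEFORE_OVERLAP), and an optional typed value
(coded, quantity-with-units, or free text). Spans are 0-based half-open
character offsets. The format's JSON Schema is generated from the same
pydantic model that validates input, so the published schema and the
validator cannot drift. Document dates are required: episode ordering
needs a total order on time, and mentions without their own temporal
anchor inherit the document date under document-time-relation semantics.

**Level 2 — compositions.** Within one document, mentions merge by the
key *(concept code, polarity, resource kind)* into event details typed by
a six-member FHIR DSTU2 resource subset (Condition, Patient, Observation,
BodySite, Procedure, MedicationStatement; the semantic-class mapping is
total, with Patient populated from document metadata rather than
mentions). Negated and affirmed mentions of a concept never merge.
Uncertainty keeps the maximum among contributors. Value reconciliation
keeps the most specific non-null value — structured (coded or quantity)
outranks free text — and preserves any distinct competing values as a
conflict annotation on the event detail rather than discarding them,
because downstream rules (assay precedence in particular) may need that
evidence. Merging is deterministic and independent of mention input
order. There is no cross-document coreference at this level; aggregation
across documents belongs to Levels 3 and 4.

**Level 3 — episodes.** Episode boundaries are declarative. For each
(episode type, phase) the configuration names start-trigger, end-trigger
and member concept sets (codes or lexicon categories, expanded and
checked at load time). The bundled defaults: a Diagnostic phase opens at
the first affirmed sign/symptom/imaging-finding trigger and closes at the
first cancer-diagnosis Condition; Treatment opens at the first
therapeutic medication or procedure after diagnosis and closes at the
last such event; FollowUp spans post-treatment surveillance findings; a
MetastaticTumor episode opens when a metastasis-coded finding appears;
Recurrence is configured as an additional episode type beyond the two
core ones. Events are assigned by trigger-set membership plus temporal
containment; an event matching two episodes joins both and is flagged
multi-assigned, and events matching none are retained in an unclassified
bucket. Episodes of one type with two or more phases are wrapped in a
parent episode (phase `None`) whose interval covers its children — a lone
phase episode stands top-level, keeping simple courses simple. Temporal
anchoring is deliberately coarse (event time = document date; BEFORE
events are unbounded-before and never anchor boundaries); full
interval-algebra reasoning is out of scope. Ties between simultaneous
trigger candidates break on the earliest document id, so segmentation is
deterministic.

**Level 4 — phenotypes.** Declarative rules (conjunctive condition over
concept/category, resource kind, polarity, assay-method qualifier,
optional episode context; no arbitrary code) are forward-applied in
priority order, lower number = higher precedence. Cancer-scoped rules
assert onto the single Cancer entity; tumor-scoped rules assert onto the
Tumor(s) owning the matched event. Tumors partition the course one per
(episode type, body site), sites taken from affirmed BodySite events in
the type's episodes with a configured default (breast) for primary and
locally recurrent tumors. Events outside every episode still attach to
every tumor for tumor-scoped evidence — unambiguous when there is a
single tumor (the common case for late receptor panels), conservative
and conflict-visible otherwise.

Per (entity, attribute), candidate assertions fold into valid-period
segments: a later assertion supersedes the current one — closing its
period and opening a new one — only when its priority number is no worse.
An equal-priority later value therefore records genuine phenotype change
(ER positive acquiring ER negative yields two time-scoped phenotype
records with disjoint periods), while a weaker-method result can never
displace a stronger one: an IHC value never overrides a FISH value in
either temporal order, which is exactly the assay-precedence rule the
ruleset encodes (FISH priority 10, IHC priority 20). Same-date conflicts
resolve by priority, then most recent document, then document id; every
suppressed competitor is recorded as a conflict annotation for audit.
Negated events never produce affirmative assertions. A phenotype record
is cut at every date on which any attribute changes, so records of one
entity always carry pairwise disjoint valid periods.

Assay methods are post-coordinated: the method qualifier (IHC, FISH)
rides on the observation concept in the lexicon and is copied onto the
event detail, rather than pre-composing marker × method × interpretation
concepts. Stage is asserted only from stated stage mentions — no
TNM-to-stage-group derivation is computed, since inventing staging tables
would outrun the evidence in the record. Co-morbidities attach at the
patient level (`patient_attributes`), as does date of death (also
mirrored as a Cancer outcome); both are produced by dedicated summarizer
steps rather than scoped rules. A positive germline test (BRCA1, PALB2)
materializes a germline sequence variation cross-referenced to the
Sequence Ontology `sequence_variant` class (SO:0001060).

**Provenance.** All `wasDerivedFrom` edges live in one central acyclic
graph per record (derived → source), rather than embedded per object, so
closure and path queries need no object traversal. Event details point to
their mentions, episodes to their events, tumors to their episodes, the
cancer to its tumors, attribute assertions to their matched events, and
phenotype records to their assertions — hence the transitive closure of
any Level-4 assertion reaches at least one mention, an invariant the
validator and the acceptance checks both enforce. Edge insertion rejects
cycles outright.

## Queries

The five competency-question categories run over summarized records as
pure functions. Durations are expressed in days with inclusive bounds
("eight weeks" = 56 days). Criteria queries are negation-aware: negated
polarity selects patients whose mentions of the concept are all negated.
Stratification returns within-stratum counts and proportions with
0-count rows retained and performs no statistical testing. Triangulation
uses the document-type provenance carried on event details. Schema
availability validates values (dates must parse; configured value sets
and TNM patterns must match) and excludes invalid ones with a warning.

## The synthetic generator

The generator emulates the document structure of a breast-cancer course:
imaging with a mass finding, biopsy, a pathology panel (diagnosis,
T/N/M, stage, ER/PR/HER2 by IHC, BRCA1 test, tumor size, Nottingham
score), then optionally treatment documents, a metastatic imaging
document, a recurrence diagnosis, and a death summary, on a synthetic
calendar (nominal 14-day inter-document gap, ±3 days jitter). Defaults,
chosen once as realistic figures for a breast-cancer cohort: ER+ 0.75,
PR+ 0.65, HER2+ 0.2, BRCA1 carrier 0.1, lobular histology 0.2, in-situ
fraction 0.15 (primary-only scenario), mention duplication 0.3, negated
distractor rate 0.1, HER2 IHC/FISH conflict 0.1, death rate 0. When a
conflict is injected, the FISH value is the ground truth, by the assay
precedence above. All randomness flows through a single seeded generator
and files are written with sorted keys, so output is byte-reproducible
per seed. A separate perturbation step injects negated duplicates,
discordant HER2 pairs, and unanchored document-time relations into an
existing record while preserving schema validity; all-zero noise is the
identity.

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: narrative text and NLP extraction error
(mentions are exact), cross-document coreference ambiguity, conflicting
or missing document dates, multiple synchronous primaries, non-breast
vocabularies, and realistic treatment-regimen structure. Results on
generator output demonstrate correctness of the abstraction machinery,
not NLP robustness.

## Numerical and design choices

- Identifiers are opaque strings namespaced by level prefix
  (`men:`/`doc:`/`evt:`/`epi:`/`phe:`/`tum:`/`can:`/`trt:`/`out:`/`var:`),
  so level membership is decidable from an id.
- Attribute value sets and TNM patterns ship as editable configuration in
  the bundled lexicon (~55 concepts), not hard-coded, mirroring how such
  vocabularies are maintained outside the code.
- The FHIR export targets DSTU2-era resource shapes. Each resource also
  carries a `source` extension with the object's canonical JSON, which is
  what makes export → import bit-exact; consumers that only speak FHIR can
  ignore it.
- RDF output is canonically serialized as sorted N-Triples because Turtle
  serializers do not guarantee stable triple order across processes; a
  Turtle rendering is available for reading.
- Degenerate inputs: an empty record validates and summarizes to an empty
  summary; a course with no matching rules leaves attributes null; an
  episode with no closing trigger closes at its last member event so both
  boundary dates are always set.

## Problem sizes

The test suite and the acceptance script run on deliberately small
cohorts: 100 patients for the precedence check, 20 seeds × 3 scenarios ×
1 patient for recovery and provenance completeness, 100-node random DAGs
for the closure oracle. These sizes were chosen as the smallest that
exercise every code path and rate; the pipeline itself is linear in
mentions and has no per-cohort state.

## Known limitations

Single-cancer assumption (one Cancer entity per patient); one episode per
(type, phase) per course; coarse temporal anchoring; no TNM→stage
derivation; assay precedence currently modeled for HER2 (the only
bundled marker with two assay concepts); rule conditions are conjunctive
only. Reading native cTAKES XMI/CAS output is a documented extension
point of the ingest layer, not implemented; only the JSON interchange is
supported.
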