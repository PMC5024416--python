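"""oncophen: multi-level computable cancer phenotypes.

A reference implementation of a four-level cancer-phenotype information
model: span-anchored mentions from clinical documents (Level 1) are merged
into per-document FHIR-style compositions (Level 2), segmented into typed
and phased episodes along a disease course (Level 3), and abstracted by
prioritized declarative rules into provenance-linked patient, cancer and
tumor phenotype summaries (Level 4), queryable through competency-question
operations.
"""

from .model import (PatientRecord, ProvenanceGraph, validate_record,
                    derivation_closure, derivation_path)
from .ingest import (read_mention_file, write_mention_file, assemble_patient,
                     mention_file_schema)
from .compose import map_resource_kind, build_composition, compose_record
from .episodes import (EpisodeConfig, load_episode_config,
                       default_episode_config, segment, segment_record,
                       episode_timeline)
from .rules import (Ruleset, load_rules, default_ruleset, evaluate_rule,
                    assign_tumors, summarize, summarize_record)
from .query import (query_criteria, query_event_interval, stratify,
                    triangulate, schema_availability, get_attribute)
from .simulate import (Scenario, ScenarioConfig, PerturbConfig, generate,
                       perturb, write_patient_files)
from .export import (export_fhir_json, import_fhir_json, export_rdf,
                     rdf_to_canonical_nt, rdf_to_turtle)
from .lexicon import Lexicon, default_lexicon

__version__ = "0.1.0"


def run_pipeline(record: PatientRecord,
                 episode_config: EpisodeConfig | None = None,
                 ruleset: Ruleset | None = None) -> PatientRecord:
    """Run the full abstraction pipeline on a documents-only record.

    Equivalent to ``summarize_record(segment_record(compose_record(r)))``
    with the bundled default configuration; the record is filled in place
    and returned.
    """
    compose_record(record)
    segment_record(record, episode_config)
    summarize_record(record, ruleset)
    return record
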