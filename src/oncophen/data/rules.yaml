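# Default breast-cancer summarization ruleset.
#
# Rules are declarative: a conjunctive condition pattern over event details
# (concept codes or lexicon categories, resource kind, polarity, assay method
# qualifier, optional episode context) plus an action asserting one phenotype
# attribute or manifestation. Lower priority number = higher precedence.
#
# Receptor-status rules encode assay-method precedence: a FISH result
# (priority 10) always outranks an IHC result (priority 20) for the same
# attribute, whatever their document order.
rules:
  - id: her2-by-fish
    priority: 10
    scope: tumor
    condition: {concepts: [C900213], resource_kind: Observation, polarity: affirmed, method: FISH}
    action: {attribute: "manifestation:her2_status", manifestation_kind: Molecular,
             value: {from: event_value}}
  - id: her2-by-ihc
    priority: 20
    scope: tumor
    condition: {concepts: [C900212], resource_kind: Observation, polarity: affirmed, method: IHC}
    action: {attribute: "manifestation:her2_status", manifestation_kind: Molecular,
             value: {from: event_value}}
  - id: er-by-ihc
    priority: 21
    scope: tumor
    condition: {concepts: [C900210], resource_kind: Observation, polarity: affirmed, method: IHC}
    action: {attribute: "manifestation:er_status", manifestation_kind: Molecular,
             value: {from: event_value}}
  - id: pr-by-ihc
    priority: 22
    scope: tumor
    condition: {concepts: [C900211], resource_kind: Observation, polarity: affirmed, method: IHC}
    action: {attribute: "manifestation:pr_status", manifestation_kind: Molecular,
             value: {from: event_value}}

  - id: cancer-type
    priority: 40
    scope: cancer
    condition: {concepts: [category:primary_dx, category:met_dx, category:recurrence_dx],
                resource_kind: Condition, polarity: affirmed}
    action: {attribute: cancer_type,
             value: {from: map, map: {C4194: carcinoma, C4018: carcinoma, C2924: carcinoma,
                                      C4019: carcinoma, C36263: carcinoma, C153519: carcinoma,
                                      C7771: carcinoma}}}
  - id: cancer-histology
    priority: 41
    scope: cancer
    condition: {concepts: [category:primary_dx], resource_kind: Condition, polarity: affirmed}
    action: {attribute: histologic_type,
             value: {from: map, map: {C4194: ductal, C2924: ductal, C4018: lobular, C4019: lobular}}}
  - id: cancer-extent
    priority: 42
    scope: cancer
    condition: {concepts: [category:primary_dx], resource_kind: Condition, polarity: affirmed}
    action: {attribute: tumor_extent,
             value: {from: map, map: {C4194: invasive, C4018: invasive, C2924: in-situ,
                                      C4019: in-situ}}}
  - id: cancer-stage
    priority: 43
    scope: cancer
    condition: {concepts: [C28074], resource_kind: Observation, polarity: affirmed}
    action: {attribute: cancer_stage, value: {from: event_value}}
  - id: t-classification
    priority: 44
    scope: cancer
    condition: {concepts: [C48885], resource_kind: Observation, polarity: affirmed}
    action: {attribute: t_classification, value: {from: event_value}}
  - id: n-classification
    priority: 45
    scope: cancer
    condition: {concepts: [C48884], resource_kind: Observation, polarity: affirmed}
    action: {attribute: n_classification, value: {from: event_value}}
  - id: m-classification
    priority: 46
    scope: cancer
    condition: {concepts: [C48883], resource_kind: Observation, polarity: affirmed}
    action: {attribute: m_classification, value: {from: event_value}}

  - id: tumor-type
    priority: 50
    scope: tumor
    condition: {concepts: [category:primary_dx, category:met_dx, category:recurrence_dx],
                resource_kind: Condition, polarity: affirmed}
    action: {attribute: cancer_type,
             value: {from: map, map: {C4194: carcinoma, C4018: carcinoma, C2924: carcinoma,
                                      C4019: carcinoma, C36263: carcinoma, C153519: carcinoma,
                                      C7771: carcinoma}}}
  - id: tumor-histology
    priority: 51
    scope: tumor
    condition: {concepts: [category:primary_dx], resource_kind: Condition, polarity: affirmed}
    action: {attribute: histologic_type,
             value: {from: map, map: {C4194: ductal, C2924: ductal, C4018: lobular, C4019: lobular}}}
  - id: tumor-extent
    priority: 52
    scope: tumor
    condition: {concepts: [category:primary_dx, category:met_dx], resource_kind: Condition,
                polarity: affirmed}
    action: {attribute: tumor_extent,
             value: {from: map, map: {C4194: invasive, C4018: invasive, C2924: in-situ,
                                      C4019: in-situ, C36263: metastatic, C153519: metastatic}}}

  - id: brca1-status
    priority: 60
    scope: cancer
    condition: {concepts: [C900220], resource_kind: Observation, polarity: affirmed}
    action: {attribute: "manifestation:brca1_status", manifestation_kind: Molecular,
             value: {from: event_value}}
  - id: palb2-status
    priority: 61
    scope: cancer
    condition: {concepts: [C900221], resource_kind: Observation, polarity: affirmed}
    action: {attribute: "manifestation:palb2_status", manifestation_kind: Molecular,
             value: {from: event_value}}
  - id: tumor-size
    priority: 62
    scope: tumor
    condition: {concepts: [C900230], resource_kind: Observation, polarity: affirmed}
    action: {attribute: "manifestation:tumor_size", manifestation_kind: Clinical,
             value: {from: event_value}}
  - id: nottingham-score
    priority: 63
    scope: tumor
    condition: {concepts: [C900231], resource_kind: Observation, polarity: affirmed}
    action: {attribute: "manifestation:nottingham_score", manifestation_kind: Clinical,
             value: {from: event_value}}
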