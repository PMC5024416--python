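# Default episode-boundary configuration.
#
# Each (episode_type, phase) names start/end trigger concept sets and the
# member concept set used for event assignment. Entries are concept codes or
# "category:<name>" references expanded against the lexicon at load time.
#
# The Diagnostic phase opens at the first affirmed sign/symptom/imaging-finding
# trigger and closes at the first cancer-diagnosis Condition; Treatment opens
# at the first therapeutic medication/procedure after diagnosis and closes at
# the last such event; FollowUp spans post-treatment surveillance events. A
# MetastaticTumor episode opens when a metastasis-coded finding or Condition
# appears. Recurrence is a configurable extension beyond the two core types.
episode_types:
  PrimaryTumor:
    phases:
      Diagnostic:
        start_triggers: [category:sign_finding, category:imaging_procedure]
        end_triggers: [category:primary_dx]
        members:
          - category:sign_finding
          - category:imaging_procedure
          - category:biopsy_procedure
          - category:primary_dx
          - category:tnm
          - category:stage_obs
          - category:receptor_status
          - category:genetic_test
          - category:tumor_metrics
          - category:primary_site
      Treatment:
        requires_phase: Diagnostic
        end_mode: last          # closes at the LAST therapeutic event
        start_triggers: &tx_triggers
          - category:therapeutic_procedure
          - category:chemotherapy
          - category:targeted_therapy
          - category:hormonal_therapy
        end_triggers: *tx_triggers
        members: *tx_triggers
      FollowUp:
        requires_phase: Treatment
        end_mode: last
        start_triggers: [category:followup_finding]
        end_triggers: [category:followup_finding]
        members: [category:followup_finding]
  MetastaticTumor:
    phases:
      Diagnostic:
        start_triggers: [category:met_finding, category:met_imaging, category:met_dx]
        end_triggers: [category:met_dx]
        members:
          - category:met_finding
          - category:met_imaging
          - category:met_dx
          - category:met_site
  Recurrence:
    phases:
      Diagnostic:
        start_triggers: [category:recurrence_dx]
        end_triggers: [category:recurrence_dx]
        members: [category:recurrence_dx]
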