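"""The five competency-question query categories over a synthetic cohort.

Generates a mixed cohort (metastatic and treated-with-recurrence courses,
some deaths), summarizes every record, and runs one query of each
category: clinical criteria, event interval, stratification,
triangulation, and schema availability.
"""

from oncophen import (ScenarioConfig, generate, query_criteria,
                      query_event_interval, run_pipeline,
                      schema_availability, stratify, triangulate)

cohort = []
for scenario, seed in [("primary_then_metastasis", 21),
                       ("treated_with_recurrence", 22)]:
    for patient in generate(ScenarioConfig(seed=seed, scenario=scenario,
                                           n_patients=6, death_rate=0.5,
                                           death_gap_days=7)):
        record = run_pipeline(patient.record())
        record.patient_id = f"{scenario[:4]}:{patient.patient_id}"
        cohort.append(record)

# criteria: which patients have a metastatic carcinoma mention?
hits = query_criteria(cohort, "C36263", level="mention")
print(f"criteria      metastatic carcinoma mentioned: {len(hits)} patients")

# eventrel: chemotherapy within eight weeks (56 days) of death?
hits = query_event_interval(cohort, "C456", "C28554", 56)
print(f"eventrel      chemo within 56 days of death:  {len(hits)} patients")

# stratification: tamoxifen use by ER status
frame = stratify(cohort, "manifestation:er_status", "treatment:C855")
print("stratify      tamoxifen by ER status:")
for _, row in frame.iterrows():
    print(f"                ER {row['split']:8s} treated={row['outcome']!s:5s} "
          f"n={row['count']} ({row['proportion']:.0%})")

# triangulation: tamoxifen in progress notes but never in pathology docs
hits = triangulate(cohort, "progress_note", "pathology", "C855")
print(f"triangulate   tamoxifen in notes only:        {len(hits)} patients")

# schema: for which patients is a valid date of death on file?
hits = schema_availability(cohort, "date_of_death")
print(f"schema        valid date of death on file:    {len(hits)} patients")

# The counts track the generator's choices: ER-positive treated patients
# receive tamoxifen, so the stratification splits cleanly, and only
# patients given a death document have a date of death available.
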