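# 29-item deficit-accumulation frailty index registry.
# Each item maps a raw recorded value into a deficit score in [0, 1]
# (0 = deficit absent, 1 = maximal expression).  The item list mirrors the
# harmonised domains used in ageing cohorts: functional limitations
# (ADL/IADL/mobility), self-reported health, CES-D-8 depressive symptoms,
# self-reported physician-diagnosed conditions, and cognitive status.
# Ordinal cut-offs are editable configuration, not asserted survey codings.
# Items tagged hypertension / stroke / diabetes form the exclusion set of
# the revised 26-item index.
items:
  - {name: adl_dressing,        kind: binary,  domain: functional_limitations}
  - {name: adl_walking_room,    kind: binary,  domain: functional_limitations}
  - {name: adl_bathing,         kind: binary,  domain: functional_limitations}
  - {name: adl_eating,          kind: binary,  domain: functional_limitations}
  - {name: adl_bed_transfer,    kind: binary,  domain: functional_limitations}
  - {name: adl_toileting,       kind: binary,  domain: functional_limitations}
  - {name: iadl_meals,          kind: binary,  domain: functional_limitations}
  - {name: iadl_shopping,       kind: binary,  domain: functional_limitations}
  - {name: iadl_phone,          kind: binary,  domain: functional_limitations}
  - {name: iadl_medication,     kind: binary,  domain: functional_limitations}
  - {name: iadl_money,          kind: binary,  domain: functional_limitations}
  - {name: mobility_walking,    kind: binary,  domain: functional_limitations}
  - name: self_rated_health
    kind: ordinal
    domain: self_reported_health
    # raw levels 1 (excellent) .. 5 (poor)
    levels: {1: 0.0, 2: 0.25, 3: 0.5, 4: 0.75, 5: 1.0}
  - {name: health_worse_than_before, kind: binary, domain: self_reported_health}
  - {name: cesd_depressed,      kind: binary,  domain: depressive_symptoms}
  - {name: cesd_everything_effort, kind: binary, domain: depressive_symptoms}
  - {name: cesd_restless_sleep, kind: binary,  domain: depressive_symptoms}
  - {name: cesd_felt_lonely,    kind: binary,  domain: depressive_symptoms}
  - {name: cesd_felt_sad,       kind: binary,  domain: depressive_symptoms}
  - {name: cesd_could_not_get_going, kind: binary, domain: depressive_symptoms}
  - {name: cesd_not_happy,      kind: binary,  domain: depressive_symptoms}
  - {name: cesd_not_enjoy_life, kind: binary,  domain: depressive_symptoms}
  - {name: hypertension,        kind: binary,  domain: medical_conditions, tags: [hypertension]}
  - {name: diabetes,            kind: binary,  domain: medical_conditions, tags: [diabetes]}
  - {name: stroke,              kind: binary,  domain: medical_conditions, tags: [stroke]}
  - {name: lung_disease,        kind: binary,  domain: medical_conditions}
  - {name: cancer,              kind: binary,  domain: medical_conditions}
  - {name: arthritis,           kind: binary,  domain: medical_conditions}
  - {name: cognitive_impairment, kind: binary, domain: cognitive_status}
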