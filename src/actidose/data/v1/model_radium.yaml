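model_id: free_radium
description: 'Systemic model for free radium (alkaline-earth behaviour): rapid blood
  clearance to bone surfaces and soft tissue with predominantly faecal excretion.
  Coefficient values are representative (fixture v1, user-replaceable).'
compartments:
- blood
- trab_surface
- cort_surface
- liver
- other
- colon_content
- bladder_content
source_compartment: blood
transfer:
- from: blood
  to: trab_surface
  per_h: 0.3465
- from: blood
  to: cort_surface
  per_h: 0.3465
- from: blood
  to: liver
  per_h: 0.02772
- from: blood
  to: other
  per_h: 0.4158
- from: blood
  to: colon_content
  per_h: 0.23562
- from: blood
  to: bladder_content
  per_h: 0.01386
- from: trab_surface
  to: blood
  per_h: 0.005776
- from: cort_surface
  to: blood
  per_h: 0.005776
- from: liver
  to: blood
  per_h: 0.005776
- from: other
  to: blood
  per_h: 0.01155
- from: colon_content
  to: faeces
  per_h: 0.0289
- from: bladder_content
  to: urine
  per_h: 0.231
region_map:
  blood:
  - region: '@blood'
    weight: 1.0
  liver:
  - region: Liver
    weight: 1.0
  trab_surface:
  - region: Trabecular bone surface
    weight: 1.0
  cort_surface:
  - region: Cortical bone surface
    weight: 1.0
  other:
  - region: '@soft_tissue_mass'
    weight: 1.0
  colon_content:
  - region: Left colon contents
    weight: 0.25
  - region: Right colon contents
    weight: 0.37
  - region: Rectosigmoid colon contents
    weight: 0.38
  bladder_content:
  - region: Urinary bladder content
    weight: 1.0
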