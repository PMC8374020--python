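model_id: free_thorium
description: 'Systemic model for free thorium: blood exchanging with bone surfaces,
  liver, kidneys and other soft tissue, with urinary and faecal excretion. Topology
  follows the reference thorium systemic model; coefficient values are representative
  (fixture v1, user-replaceable).'
compartments:
- blood
- liver
- kidneys
- trab_surface
- cort_surface
- other
- bladder_content
- colon_content
source_compartment: blood
transfer:
- from: blood
  to: trab_surface
  per_h: 0.03465
- from: blood
  to: cort_surface
  per_h: 0.03465
- from: blood
  to: liver
  per_h: 0.005775
- from: blood
  to: kidneys
  per_h: 0.003465
- from: blood
  to: bladder_content
  per_h: 0.00693
- from: blood
  to: colon_content
  per_h: 0.00693
- from: blood
  to: other
  per_h: 0.0231
- from: trab_surface
  to: blood
  per_h: 0.0008
- from: cort_surface
  to: blood
  per_h: 0.0008
- from: liver
  to: blood
  per_h: 0.0004
- from: kidneys
  to: bladder_content
  per_h: 0.002
- from: other
  to: blood
  per_h: 0.002
- from: bladder_content
  to: urine
  per_h: 0.231
- from: colon_content
  to: faeces
  per_h: 0.0289
region_map:
  blood:
  - region: '@blood'
    weight: 1.0
  liver:
  - region: Liver
    weight: 1.0
  kidneys:
  - region: Kidneys
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
  bladder_content:
  - region: Urinary bladder content
    weight: 1.0
  colon_content:
  - region: Left colon contents
    weight: 0.25
  - region: Right colon contents
    weight: 0.37
  - region: Rectosigmoid colon contents
    weight: 0.38
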