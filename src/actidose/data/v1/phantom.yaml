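name: adult-female-v1
description: 'Adult female reference phantom fixture: representative tissue masses
  and blood-volume fractions (user-replaceable). Regions cover the 27 source regions
  of the pipeline plus the endosteal dose target; targets are the radiosensitive
  tissues reported.'
tissues:
- name: Adipose tissue
  mass_kg: 18.0
  blood_volume_fraction: 0.192765424462
- name: Adrenals
  mass_kg: 0.013
  blood_volume_fraction: 0.001475716168
- name: Lungs
  mass_kg: 0.95
  blood_volume_fraction: 0.307338388071
- name: Brain
  mass_kg: 1.3
  blood_volume_fraction: 0.029504075334
- name: Breasts
  mass_kg: 0.5
  blood_volume_fraction: 0.01418327206
- name: Cortical bone surface
  mass_kg: 0.0005
  blood_volume_fraction: 0.0
- name: Cortical bone
  mass_kg: 3.2
  blood_volume_fraction: 0.019665967546
- name: Heart wall
  mass_kg: 0.25
  blood_volume_fraction: 0.02458502144
- name: Kidneys
  mass_kg: 0.275
  blood_volume_fraction: 0.049180290909
- name: Left colon contents
  mass_kg: 0.075
  blood_volume_fraction: 0.0
- name: Left colon wall
  mass_kg: 0.12
  blood_volume_fraction: 0.021787309538
- name: Liver
  mass_kg: 1.4
  blood_volume_fraction: 0.0
- name: Muscle
  mass_kg: 17.5
  blood_volume_fraction: 0.258147849133
- name: Ovaries
  mass_kg: 0.011
  blood_volume_fraction: 0.000491802909
- name: Pancreas
  mass_kg: 0.12
  blood_volume_fraction: 0.014757161681
- name: Red marrow
  mass_kg: 0.9
  blood_volume_fraction: 0.0
- name: Right colon contents
  mass_kg: 0.075
  blood_volume_fraction: 0.0
- name: Right colon wall
  mass_kg: 0.12
  blood_volume_fraction: 0.021787309538
- name: Rectosigmoid colon contents
  mass_kg: 0.075
  blood_volume_fraction: 0.0
- name: Rectosigmoid colon wall
  mass_kg: 0.07
  blood_volume_fraction: 0.010514477698
- name: Spleen
  mass_kg: 0.13
  blood_volume_fraction: 0.0
- name: Trabecular bone surface
  mass_kg: 0.0005
  blood_volume_fraction: 0.0
- name: Trabecular bone
  mass_kg: 0.8
  blood_volume_fraction: 0.029504075334
- name: Thymus
  mass_kg: 0.02
  blood_volume_fraction: 0.000567228402
- name: Thyroid
  mass_kg: 0.017
  blood_volume_fraction: 0.001475716168
- name: Urinary bladder content
  mass_kg: 0.2
  blood_volume_fraction: 0.0
- name: Uterus
  mass_kg: 0.08
  blood_volume_fraction: 0.002268913609
- name: Endosteal bone surface
  mass_kg: 0.0935
  blood_volume_fraction: 0.0
targets:
- Adrenals
- Brain
- Breasts
- Endosteal bone surface
- Heart wall
- Kidneys
- Liver
- Lungs
- Muscle
- Ovaries
- Pancreas
- Red marrow
- Spleen
- Thymus
- Thyroid
- Uterus
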