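provenance: actidose fixture v1 (representative; not a reference SAF dataset)
photon_mass_coefficient: 0.35
description: Charged-particle emissions absorbed in the source region (self AF 1)
  except for the explicit skeletal sub-model and contents->wall cross-fire below;
  photon self-absorption follows 1 - exp(-c m^(1/3)). Substitute reference absorbed
  fractions via CSV for research use.
entries:
- target: Endosteal bone surface
  source: Red marrow
  kinds:
  - alpha
  - beta
  - electron
  af: 0.045
- target: Endosteal bone surface
  source: Trabecular bone surface
  kinds:
  - alpha
  - beta
  - electron
  af: 0.25
- target: Endosteal bone surface
  source: Cortical bone surface
  kinds:
  - alpha
  - beta
  - electron
  af: 0.25
- target: Red marrow
  source: Trabecular bone surface
  kinds:
  - alpha
  - beta
  - electron
  af: 0.25
- target: Endosteal bone surface
  source: Red marrow
  kinds:
  - photon
  af: 0.01
- target: Left colon wall
  source: Left colon contents
  kinds:
  - beta
  - electron
  af: 0.01
- target: Right colon wall
  source: Right colon contents
  kinds:
  - beta
  - electron
  af: 0.01
- target: Rectosigmoid colon wall
  source: Rectosigmoid colon contents
  kinds:
  - beta
  - electron
  af: 0.01
- target: Left colon wall
  source: Left colon contents
  kinds:
  - photon
  af: 0.003
- target: Right colon wall
  source: Right colon contents
  kinds:
  - photon
  af: 0.003
- target: Rectosigmoid colon wall
  source: Rectosigmoid colon contents
  kinds:
  - photon
  af: 0.003
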