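description: 'RECONSTRUCTED fixed distribution for free Bi-213 (no published kinetic
  model): per-tissue TIAC pattern in MBq.h per MBq administered, anchored at run
  time to the simulation''s own vascular TIAC via reference_blood_tiac. released_fraction
  rescales the pattern for sensitivity studies (default 0.5 is the blood-borne share
  embedded in the pattern itself).'
released_fraction: 0.5
reference_blood_tiac: 0.975797
pattern:
  Adipose tissue: 0.09406
  Adrenals: 0.0007198
  Lungs: 0.15
  Brain: 0.0144
  Breasts: 0.006919
  Cortical bone: 0.009597
  Heart wall: 0.012
  Left colon wall: 0.01063
  Liver: 2.064
  Muscle: 0.126
  Ovaries: 0.0002399
  Pancreas: 0.007198
  Red marrow: 8.185
  Right colon wall: 0.01063
  Rectosigmoid colon wall: 0.005132
  Spleen: 0.4471
  Trabecular bone: 0.0144
  Thymus: 0.0002768
  Thyroid: 0.0007198
  Uterus: 0.001107
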