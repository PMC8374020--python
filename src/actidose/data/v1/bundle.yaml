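version: v1
description: actidose default fixture bundle
files:
  chains:
    ac225: chain_ac225.yaml
    ac227: chain_ac227.yaml
  phantom: phantom.yaml
  models:
    free_thorium: model_thorium.yaml
    free_radium: model_radium.yaml
  bi213_distribution: bi213_distribution.yaml
  saf: saf.yaml
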