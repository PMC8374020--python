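name: ac225
description: Ac-225 decay series to stable Bi-209. Half-lives and branch fractions
  from standard nuclear data; per-decay mean emission energies are representative
  yield-weighted values (fixture v1, user-replaceable).
nuclides:
- name: Ac-225
  half_life: 238.08
  unit: h
  emissions:
    alpha: 5.83
    electron: 0.0216
    photon: 0.0179
- name: Fr-221
  half_life: 4.8
  unit: min
  emissions:
    alpha: 6.3
    electron: 0.01
    photon: 0.031
- name: At-217
  half_life: 32.3
  unit: ms
  emissions:
    alpha: 7.065
    photon: 0.0016
- name: Bi-213
  half_life: 45.61
  unit: min
  emissions:
    alpha: 0.1287
    beta: 0.435
    electron: 0.0324
    photon: 0.1336
- name: Po-213
  half_life: 3.72
  unit: us
  emissions:
    alpha: 8.376
- name: Tl-209
  half_life: 2.161
  unit: min
  emissions:
    beta: 0.659
    photon: 2.15
- name: Pb-209
  half_life: 3.234
  unit: h
  emissions:
    beta: 0.198
- name: Bi-209
  stable: true
branches:
- parent: Ac-225
  daughter: Fr-221
  fraction: 1.0
- parent: Fr-221
  daughter: At-217
  fraction: 1.0
- parent: At-217
  daughter: Bi-213
  fraction: 1.0
- parent: Bi-213
  daughter: Po-213
  fraction: 0.9784
- parent: Bi-213
  daughter: Tl-209
  fraction: 0.0216
- parent: Po-213
  daughter: Pb-209
  fraction: 1.0
- parent: Tl-209
  daughter: Pb-209
  fraction: 1.0
- parent: Pb-209
  daughter: Bi-209
  fraction: 1.0
fates:
  Ac-225:
    mode: FREE_MODEL
    model: antibody
  Fr-221: AT_PARENT_SITE
  At-217: AT_PARENT_SITE
  Bi-213:
    mode: FREE_MODEL
    model: bi213_fixed_distribution
  Po-213: AT_PARENT_SITE
  Tl-209: AT_PARENT_SITE
  Pb-209: AT_PARENT_SITE
  Bi-209: AT_PARENT_SITE
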