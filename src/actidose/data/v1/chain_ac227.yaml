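name: ac227
description: Ac-227 decay series to stable Pb-207. The 1% branch to Fr-223 is carried
  for atom bookkeeping but discarded for dosimetry. Emission energies are representative
  yield-weighted per-decay means (fixture v1, user-replaceable).
nuclides:
- name: Ac-227
  half_life: 21.77
  unit: y
  emissions:
    alpha: 0.0495
    beta: 0.0161
    electron: 0.0006
    photon: 0.0002
- name: Th-227
  half_life: 18.68
  unit: d
  emissions:
    alpha: 5.9
    electron: 0.0528
    photon: 0.106
- name: Fr-223
  half_life: 22.0
  unit: min
  emissions:
    beta: 0.39
    photon: 0.059
- name: Ra-223
  half_life: 11.43
  unit: d
  emissions:
    alpha: 5.665
    electron: 0.0756
    photon: 0.1338
- name: Rn-219
  half_life: 3.96
  unit: s
  emissions:
    alpha: 6.755
    electron: 0.0021
    photon: 0.0582
- name: Po-215
  half_life: 1.781
  unit: ms
  emissions:
    alpha: 7.386
    photon: 0.0002
- name: Pb-211
  half_life: 36.1
  unit: min
  emissions:
    beta: 0.4471
    electron: 0.0114
    photon: 0.0631
- name: Bi-211
  half_life: 2.14
  unit: min
  emissions:
    alpha: 6.55
    beta: 0.01
    electron: 0.0017
    photon: 0.0465
- name: Tl-207
  half_life: 4.77
  unit: min
  emissions:
    beta: 0.4926
    electron: 0.0014
    photon: 0.0022
- name: Po-211
  half_life: 0.516
  unit: s
  emissions:
    alpha: 7.442
    photon: 0.0055
- name: Pb-207
  stable: true
branches:
- parent: Ac-227
  daughter: Th-227
  fraction: 0.99
- parent: Ac-227
  daughter: Fr-223
  fraction: 0.01
- parent: Th-227
  daughter: Ra-223
  fraction: 1.0
- parent: Fr-223
  daughter: Ra-223
  fraction: 1.0
- parent: Ra-223
  daughter: Rn-219
  fraction: 1.0
- parent: Rn-219
  daughter: Po-215
  fraction: 1.0
- parent: Po-215
  daughter: Pb-211
  fraction: 1.0
- parent: Pb-211
  daughter: Bi-211
  fraction: 1.0
- parent: Bi-211
  daughter: Tl-207
  fraction: 0.99724
- parent: Bi-211
  daughter: Po-211
  fraction: 0.00276
- parent: Tl-207
  daughter: Pb-207
  fraction: 1.0
- parent: Po-211
  daughter: Pb-207
  fraction: 1.0
fates:
  Ac-227:
    mode: FREE_MODEL
    model: antibody
  Th-227:
    mode: SPLIT
    bound_fraction: 0.7
    model: free_thorium
  Fr-223: DISCARD
  Ra-223:
    mode: FREE_MODEL
    model: free_radium
  Rn-219: AT_PARENT_SITE
  Po-215: AT_PARENT_SITE
  Pb-211: AT_PARENT_SITE
  Bi-211: AT_PARENT_SITE
  Tl-207: AT_PARENT_SITE
  Po-211: AT_PARENT_SITE
  Pb-207: AT_PARENT_SITE
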