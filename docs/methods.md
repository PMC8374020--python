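# Methods

`actidose` estimates the organ absorbed-dose burden contributed by the
Ac-227 radionuclidic impurity in accelerator-produced Ac-225
("225/7Ac") when a 225/7Ac-labeled antibody is administered
intravenously against a hematologically distributed target (e.g. CD33 in
acute myeloid leukemia). The pipeline couples a nonlinear
antibody–antigen pharmacokinetic model, linear systemic models for free
thorium and radium, decay-chain bookkeeping, time-integrated activity
coefficients (TIACs) and MIRD S-value dosimetry.

## Model structure

### Antibody–antigen model

Radiolabeled antibody is administered into a distribution volume
`Vd` (plasma plus the extracellular fluid of liver, spleen and red
marrow). Three compartments:

1. **vascular** — free antibody; binds antigen with the saturable
   mass-action rate `k(2,1) = k_on · [free antigen]`, is cleared with
   half-time `Tc`;
2. **bound** — antigen-bound antibody; dissociates at `k_off`,
   internalizes with half-time `Ti`;
3. **internalized** — no longer dissociable; removed by intracellular
   catabolism with half-time `Tci`.

Free antigen is `Ag0 − bound − internalized` with a smooth floor at
zero (width 1e-9 nmol, a numerical-robustness device that is inert at
trace occupancy). The biology (nmol of antibody) is independent of the
radiolabel; the label activity in compartment *i* is the biological
content scaled by `exp(−λ_phys t)`, and the label's sink partitioning
(excreted by clearance/catabolism vs. physically decayed) is integrated
alongside in the same ODE so that label conservation holds to solver
tolerance (LSODA, rtol 1e-10, atol 1e-14).

Parameters (defaults; units):

| parameter | default | meaning |
|---|---|---|
| `Ag0` | 14.95 nmol | antigen pool: 90% of 1 kg (1e12) antigen-positive cells in `Vd` |
| `Ab0` | 1.0 nmol | administered antibody (not published; trace-level default, sub-saturating — see design choices) |
| `Vd` | 3.8 L | distribution volume |
| `k_on` | 0.5 /(nM·h) | association rate (nanomolar interpretation — see design choices) |
| `k_off` | 0.003 /h | dissociation rate |
| `Tc` | 40 h | vascular clearance half-time |
| `Ti` | 0.5 h | internalization half-time |
| `Tci` | 100 h | catabolism half-time |
| `f_L1`, `f_S1` | 0.18, 0.12 | liver / spleen ECF share of the vascular compartment |
| `f_L2`, `f_S2` | 0.08, 0.06 | liver / spleen share of antigen-positive cells |
| `V_RMECF` | 0.22 L | red-marrow ECF volume |

### Impurity bookkeeping

Per MBq of administered 225/7Ac, an activity fraction
`f_ac227 = 0.007` is Ac-227 (0.7%, the injection-time impurity level
after processing delay). The Ac-227-labeled antibody follows the same
biology with Ac-227's decay constant (recomputed, not merely rescaled
from the Ac-225 curve; the difference is reported as a provenance
diagnostic and is small because physical decay of a 21.77-y nuclide is
negligible over the simulated horizon).

Ac-227 decays 99% by beta emission to Th-227. A fraction `f_ab = 0.7`
of the generated Th-227 remains antibody-conjugated (beta decay is not
energetically disruptive enough to reliably break the chelate, by
analogy with Bi-212 retention after Pb-212 decay); the remaining 30%
enters the free-thorium systemic model *as it is created* (production
term, models uncoupled).

**Bound Th-227 is transported generation-aware.** Daughter atoms appear
in each antibody compartment at rate `0.99 · f_ab ·` (local Ac-227
label decay rate) and subsequently follow the antibody model's
instantaneous flows — a linear, time-varying label system (time-varying
because binding is saturable). This is deliberately *not* the shortcut
of reusing the t=0 antibody curve scaled by `f_ac227·f_ab`: that
shortcut implicitly places the entire eventual Th-227 inventory on the
antibody at injection time and overstates the bound-thorium TIAC by
roughly a factor of six (with `Tci = 100 h` and the 18.68-d Th-227
half-life, only `λ_Th/(λ_Th+k_cat) ≈ 0.18` of antibody-borne thorium
decays before the carrier is catabolized). The implementation is
verified against a brute-force coupled parent+daughter ODE.

All Ra-223 generated by Th-227 decay — bound or free — feeds the
free-radium model. The two production sources are propagated as
separate dose components so that rescaling to other `f_ac227`/`f_ab`
assumptions is algebraically exact (see below).

Label released by catabolism or vascular clearance is booked as
excreted: chelated metal freed from a catabolized antibody is assumed
to clear without further organ residence rather than re-entering a
free-metal model.

### Free thorium, free radium, free Bi-213

The free-Th-227 and free-Ra-223 systemic models are linear first-order
compartment systems (blood exchanging with bone surfaces, liver,
kidneys [thorium], other soft tissue, and urinary/faecal excretion
paths). Their *topology* follows the reference systemic models for
thorium and for alkaline-earth elements; the *coefficient values* are
representative fixtures (the reference publications' numeric
coefficients are not reproduced here) and are user-replaceable YAML.
Every derived output carries the fixture version.

Free Bi-213 (in the Ac-225 chain) has no published kinetic model; the
package ships a RECONSTRUCTED fixed per-tissue TIAC pattern, flagged as
such in the fixture file. At run time the pattern is anchored to the
simulation's own vascular TIAC (the pattern is one-half of the
blood-apportioned antibody column for purely blood-perfused tissues, so
blood anchoring keeps all cross-tissue orderings independent of the
antibody model's vascular residence time). A `released_fraction`
parameter rescales it for sensitivity studies.

### Daughter fate policies

- Fr-221 and At-217 decay at the Ac-225 decay site (TIAC inherited at
  net yield ≈ 1; this is why they share a column with the parent).
- Po-213, Tl-209, Pb-209 decay at the Bi-213 site (net yields 0.9784,
  0.0216, 1.0).
- Rn-219, Po-215, Pb-211, Bi-211, Tl-207, Po-211 decay at the Ra-223
  site (Tl-207 at 0.99724, Po-211 at 0.00276).
- The 1% Ac-227 → Fr-223 branch is carried in the chain for atom
  conservation but DISCARDed for dosimetry (its dose contribution is
  negligible at impurity level); the alpha energy of that branch is
  still credited to Ac-227's own emission inventory.
- Nuclides with net yield < 1e-6 from the chain head are dropped at
  chain load.

## TIAC integration and apportionment

Activity curves are integrated by the trapezoidal rule on a
logarithmically dense grid (default 400 points, 0–5000 h; the horizon
covers > 30 catabolism half-times and ≥ 10 physical half-lives of every
species with its own kinetics). Beyond the horizon an analytic
single-exponential tail is added, with the rate fitted log-linearly
over the last factor-of-two of the time axis; curves still in uptake at
the horizon get no tail (truncated integral, under-estimate). Halving
the grid density moves TIACs by < 0.1%.

Vascular-compartment TIAC splits into liver ECF (`f_L1`), spleen ECF
(`f_S1`), red-marrow ECF (`V_RMECF/Vd`) and a blood remainder
apportioned over all tissues by blood-volume fraction; bound +
internalized TIAC splits across antigen-positive-cell sites (`f_L2`
liver, `f_S2` spleen, remainder red marrow). The packaged blood-volume
fractions reproduce the blood-apportionment pattern embedded in the
antibody-model TIAC ratios across purely blood-perfused tissues, with
liver/spleen/red marrow carrying no extra blood share (their vascular
content is already covered by the ECF split); they are labeled
representative and are user-replaceable. The systemic models' "other
soft tissue" compartment is spread over parenchymal soft tissue by
mass, which yields the physically expected uniform dose concentration
(tissue mass cancels).

## Dosimetry

MIRD S-value formalism: `D(target) = Σ_sources TIAC(source) ×
S(target←source)`, with `S = Σ_kinds E_kind · 3.6e9 · 1.602e-13 ·
AF / m_target` reported separately for alpha, beta, electron and photon
emissions. **RBE is never applied**; the per-kind split carries all the
information needed to apply one downstream.

The packaged absorbed-fraction set is a simple, clearly labeled
fixture, *not* a reference SAF dataset: charged particles are absorbed
where emitted (self-AF 1, cross 0) except for an explicit skeletal
sub-model — red-marrow sources irradiate the endosteal layer
(AF 0.045), bone-surface deposits irradiate the endosteal layer
(AF 0.25) and, for trabecular surfaces, red marrow (AF 0.25) — and
contents→wall electron/photon entries; photon self-absorption follows
the mass-scaling rule `1 − exp(−0.35 m^{1/3})`. Per-decay mean emission
energies per kind are packaged per nuclide (representative
yield-weighted values). Dose-report targets are the radiosensitive
organs of the study's reporting surface (16 tissues including the
endosteal layer); excreta contents, bone surfaces and mineral bone act
as source regions only, consistent with skeletal dosimetry practice
where the radiosensitive skeletal targets are active marrow and
endosteum. Absolute dose magnitudes therefore depend on these
fixtures; rank orderings and the bound-type impurity conclusions are
the robust outputs. Users can substitute reference absorbed fractions
via CSV.

## Rescaling

`rescale_report` converts a finished run to new `(f_ac227, f_ab)`
assumptions exactly: every Ac-227-chain component is linear in
`f_ac227`; bound-thorium components (including Ra-223 produced from
bound thorium) are linear in `f_ab`, free-thorium components in
`1 − f_ab`. A fresh run at the new values agrees to floating-point
precision. Degenerate originals (`f_ab` ∈ {0, 1}, or `f_ac227 = 0`
with a nonzero target) cannot be rescaled and raise.

## Numerical choices

- Stiff-capable variable-step solver (LSODA), rtol 1e-10, atol 1e-14;
  output grid logarithmically dense from 0.01 h.
- Chain kinetics (`bateman_activities`) solved exactly via the matrix
  exponential of the branched-decay generator, with absorbing states
  for stable ends and excluded branch remainders so total atom count is
  conserved to machine precision; it serves as a test oracle, not as
  pipeline plumbing.
- All internal times in hours; half-lives converted on load (year =
  Julian year, 8766 h).
- TIAC CSV is written with `%.17g` and parsed with round-trip float
  precision, so report regeneration from a round-tripped table is
  bit-identical, and identical configurations produce bit-identical
  outputs (the pipeline has no stochastic elements; the seed parameter
  feeds only optional noise in the synthetic-curve generator).
- Ties in tissue ranking break alphabetically.

## Design choices made where the inputs were open

- **`Ab0` (administered antibody amount)** is not published. Default
  1 nmol — trace relative to `Ag0 = 14.95 nmol`, the standard
  assumption for radiopharmaceutical dosing — and exposed as a config
  field for sensitivity analysis. At trace occupancy the binding rate
  is effectively constant, `k(2,1) ≈ 1.97 /h`.
- **`k_on` units**: the published table prints "0.5 M⁻¹h⁻¹", which is
  physically implausible for an antibody on-rate (it would give a
  binding half-time of years). Interpreted as 0.5 per (nM·h)
  (= 5e8 M⁻¹h⁻¹), consistent with typical antibody association
  kinetics and with the model's published behaviour (rapid binding of
  the injected antibody).
- **`f_ac227` default 0.007**: the parameter table and abstract state a
  0.7% Ac-227 activity fraction at administration; the package takes
  that as the scenario definition. (The source's results text mentions
  "0.07%" for the same quantity; the provenance block records the
  value actually used.)
- **Generation-aware bound thorium** (see above) rather than curve
  rescaling: matches the coupled-ODE oracle and avoids a ~6x
  overestimate of bound-Th TIAC.

## What the synthetic inputs do and do not emulate

The fixture bundle emulates the *structure* of the study inputs: the
antibody model with its published parameter values, systemic models
with the published topologies, a 27-source-region adult-female phantom,
and per-decay mean energies for both chains. It does not reproduce
reference-grade absorbed fractions, emission spectra, or the reference
systemic-model coefficients, so absolute organ doses from the default
fixtures are indicative, not reference values. Passing tests
demonstrate correctness of the kinetics, bookkeeping, integration and
dose algebra, plus robustness of rank-order conclusions — not
agreement with a reference phantom calculation.

## Known limitations

- Lumped-parameter kinetics: no spatial gradients or vascular
  transport; applicable to rapidly accessible, hematologically
  distributed targets only, and to antibody carriers only.
- No photon cross-fire between distinct organs (photon dose is
  self-absorption only), so photon-only targets (e.g. eye lens) are
  not reported.
- No tumor/lesion dosimetry; normal tissues only.
- Free Bi-213 distribution is a reconstruction, not a kinetic model;
  its daughters inherit its sites.
- The adult-female phantom is the only phantom; no patient-specific or
  pediatric variants.
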