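# Methods

## Overview

`ncgamma` models the discrimination of neutron-capture prompt gammas from
all other radiation reaching a detector during pulsed ion-beam irradiation
of a target containing a ¹⁰B or ¹⁵⁷Gd neutron-capture insert (NCI). The
pipeline is: pulsed-beam timing → synthetic labelled phase space → shield
and detector response → temporal-mask + energy-window acceptance →
TP/FP/TN/FN classification → sensitivity / selectivity metrics and grid
optimisation. Every stage is deterministic under a fixed seed.

The package does not transport particles. The phase-space generator emits
arrivals at the detector face directly, with energy spectra, per-primary
yields and arrival-time laws chosen to reproduce the published qualitative
structure of the radiation field. Consequently *absolute* sensitivities and
R_TF values are properties of the calibration, not predictions; the
quantities the model does predict are structural — which mask, period and
shield choices optimise discrimination, and in which direction a design
change moves R_TF.

## Beam model

The beam micro-structure is a pulse train with period 200 ns and an 11 ns
beam-on window (duty cycle 5.5 %), repeated over a macroscopic irradiation
of 1 µs–100 ms. Primaries are injected at a constant rate within each
nano-spill: deterministically at constant stride by default (making small-n
cases exact), or uniformly jittered via a config flag. When the primary
count does not divide evenly, the remainder goes to the earliest spills.
Delayed events keep their generating spill as the timing reference; events
after the end of irradiation are flagged post-beam and are never masked,
since masks are tied to spills.

## Phase-space components

All yields are expected arrivals at the detector face per primary ion.
They are free calibration constants (defaults in
`phase_space.DEFAULT_YIELDS`), fixed once at design time:

| component | yield | energy | arrival law |
|---|---|---|---|
| prompt lines | 0.12 | 4.44 (60 %) / 6.13 MeV (40 %) | uniform within the remainder of the spill |
| prompt continuum | 0.10 | exp(−E), 0.1–8 MeV | same |
| NCI capture | 0.06 | 478 keV (B10) or 7.94 MeV (Gd157) | log-normal thermalisation delay |
| H capture | 0.12 | 2.23 MeV | log-normal, median 10⁴ ns, σ_ln 1.8 |
| annihilation | 0.30 (saturated) | 511 keV (70 %) + scattered continuum 0.15–0.511 MeV (30 %) | build-up activity law |
| fast neutrons | 0.25 | power law E^−1.6, 1–50 MeV | time of flight, see below |
| intermediate neutrons | 0.01 | log-uniform 0.4 eV–1 MeV | log-uniform delay 50–10⁴ ns |
| thermal neutrons | 0.06 | log-uniform 0.01–0.4 eV | log-uniform delay 10⁴–10⁷ ns |

Notes on the individual laws:

* **Thermalisation delay.** Log-normal in delay, calibrated so the central
  99 % of mass spans the thermalisation support [12, 10⁶] ns (median
  √(12·10⁶) ≈ 3.5×10³ ns, σ_ln ≈ 2.2), truncated to the support. The
  support is the physical constraint; the shape is a modelling choice (a
  log-uniform alternative is available). Hydrogen capture occurs
  throughout the phantom bulk rather than at the thermal-fluence peak, so
  its delay law uses a later median (10⁴ ns) within the same support.
* **Annihilation build-up.** β⁺ activity follows A(t) ∝ 1 − exp(−λt) with
  an effective half-life of 10 ms; the expected count scales with the time
  average of A over the irradiation, so a 1 µs exposure accumulates ~10⁻⁴
  of the saturated background while 100 ms reaches ~86 %. Events are
  generated over the irradiation interval only — the post-beam decay tail
  is not modelled, a deliberate simplification (capture-delay events, by
  contrast, do extend past beam-off). 30 % of annihilation arrivals are
  phantom-scattered and carry a continuum below 511 keV; this Compton
  population is what reaches the 478 keV window at long irradiations.
* **Fast-neutron timing.** Arrival delay is kinematic: TOF(E) = 34.2/√E ns
  over the 47.32 cm detector distance, times a log-uniform path-lengthening
  factor in [1, 1.43] for in-phantom scatter. A 1 MeV neutron therefore
  arrives no later than ~49 ns after its primary, i.e. within ~60 ns of
  the spill start — the physical origin of the ¹⁰B mask optimum. The
  falling spectral index (1.6) weights the band toward slow, late
  arrivals. Geometry (distance, 60° angle) is otherwise metadata only.

Per-component event counts are Poisson with mean yield × primaries; each
component consumes an independent, content-keyed random substream, so the
stream is invariant to the order in which components are listed.

## Detector and shield response

Photons branch per event into photopeak (full energy), Compton-partial
(uniform up to the Compton edge), and single/double escape (E − 0.511,
E − 1.022 MeV; only above pair threshold); the remainder is no detection.
Energy resolution is the quoted fractional FWHM at a reference energy with
FWHM ∝ √E scaling; deposits are Gaussian-smeared and floored at zero.
Densities and resolutions follow the standard detector literature (CdTe
2.4 % at 478 keV; LSO 10.5 %, BGO 9.7 %, LaBr₃ 2.4 % at 662 keV; CZT
2.8 %). The PbWO₄ resolution entry is ambiguous in the sources; its
default (36 %) is a documented, overridable constant. Photopeak fractions
increase with density (PbWO₄ highest).

Neutron response is parametric, since the in-detector reaction chains are
not transported. Fast and intermediate neutrons interact with a per-band,
per-material probability; the deposit mixes a soft recoil exponential
(mean 0.8 MeV) with a hard branch at E_n + Q·w, w ∈ [0.3, 1) — near-full
absorption of the recoil plus reaction-gamma cascade, with Q = 6.0 MeV
(fast, inelastic) or 8.3 MeV (intermediate, resonance capture). The hard
branch is what lets a ~2 MeV neutron contaminate the 7.94 MeV window, and
its E_n + Q ceiling is what keeps neutrons below ~1.6 MeV out of it —
combined with time of flight, this produces the earlier (50 ns vs 60 ns)
mask optimum for ¹⁵⁷Gd. Thermal neutrons deposit sub-keV recoils or are
captured on detector nuclei: Cd-bearing materials re-emit their discrete
capture lines (0.558, 8.48, 9.04 MeV — none near 478 keV), while the
scintillators carry a weak summed-cascade continuum reaching ~8.3 MeV,
smallest for LSO, whose constituents have no capture lines in the 7.94 MeV
acceptance window. Per-band probabilities are calibration constants chosen
so neutron false positives dominate the early-offset background.

Shields are 1 mm front-face layers with configured thermal transmission
(Cd 10⁻³, Gd 5·10⁻⁴, B 2·10⁻³, Hf 5·10⁻³) and gamma transmission
(0.94–0.995) — constants from standard attenuation data, not computed from
cross-section libraries. Absorbed thermal neutrons emit a capture gamma
toward the detector with a solid-angle factor of 0.2; for Cd these are the
8.48 / 9.04 MeV lines whose single/double escape peaks (7.97 / 8.02 MeV)
land inside the 7.94 MeV window — the mechanism that makes Cd shielding
poisonous for a ¹⁵⁷Gd insert while boron or hafnium shielding helps. Fast
and intermediate neutrons pass unmodified.

Detector activation by thermal neutrons is available only as a constant
background-rate toggle, off by default.

## Acceptance and metrics

The energy window is line ± k·σ(line) with k = 3 by default (the window
width is not independently published; k is exposed in config and reports).
The temporal mask is half-open — an offset exactly at the mask boundary is
accepted — and post-irradiation events are always accepted. Ground truth
for "capture of interest" is capture in the NCI only; hydrogen captures
count as background. R_TF uncertainty uses first-order propagation of
independent Poisson counts, σ(R) = R√(1/TP + 1/FP), reported as ±2σ;
R_TF is reported as undefined (not infinite) when FP = 0.

## Sweeps and common random numbers

`sweep_grid` evaluates the Cartesian product of the requested axes.
Within one sweep, all masks share a single event stream, and materials,
shields and irradiation periods run on common random numbers (per-event
counter-based draws keyed on stable event ids, per-cell seeds derived from
the base seed and the scenario's insert/beam coordinates). Comparisons
within a sweep are therefore paired: the difference between two cells is
driven by the systematic effect, not by independent sampling noise, which
is what allows few-percent effects (e.g. 1 µs vs 10 µs irradiation) to
resolve at 10⁶ primaries. Independent replicates come from varying the
base seed. Ties in the arg-max are broken toward the smallest mask, then
the shortest period, then material name order.

## Problem sizes

Default sweeps use 10⁶ primaries per cell (~7×10⁵ events per stream,
about a second per cell), a scale at which all the structural results —
mask optima at 60 ns (¹⁰B/CdTe) and 50 ns (¹⁵⁷Gd/LSO), the 1 µs period
optimum, the shield directions — reproduce across seeds. The test suite
and the acceptance script both run at this scale.

## What the generator does and does not show

Passing tests demonstrate that the discrimination scheme recovers the
documented optima *given* a radiation field with the published timing and
spectral structure. They do not validate absolute fluences, detector
efficiencies or R_TF magnitudes, all of which would require full transport
physics (phantom geometry, SOBP synthesis, cross-section libraries) that
is out of scope. Other known limitations: the ¹⁵⁷Gd de-excitation model is
reduced to the 7.94 MeV line by default (the remaining lines are available
but off); the prompt continuum is a single exponential; neutron-band delay
shapes within their printed windows are modelling choices; scintillation
transport, pile-up and dead time are not modelled; the annihilation decay
tail after beam-off is not generated.
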