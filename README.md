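# ncgamma

Discrimination of neutron-capture prompt gammas during pulsed-beam particle
therapy.

## The problem

Neutron capture enhanced particle therapy (NCEPT) boosts carbon- or
helium-ion therapy by loading the tumour with a ¹⁰B or ¹⁵⁷Gd neutron-capture
agent that captures the thermal neutrons produced by beam fragmentation.
Verifying the capture dose in vivo requires counting the capture prompt
gammas — 478 keV for ¹⁰B(n,αγ), 7.94 MeV (full reaction Q) for
¹⁵⁷Gd(n,γ) — against a radiation field that also contains fragment
de-excitation gammas (4.44 / 6.13 MeV lines plus an exponential continuum),
2.23 MeV hydrogen-capture gammas from the phantom, a growing 511 keV
annihilation background from β⁺-active fragmentation products, and fast,
intermediate and thermal beam neutrons.

The discriminating physics is timing. A synchrotron beam arrives as 11 ns
nano-spills every 200 ns (duty cycle 11/200 = 5.5 %). Prompt de-excitation
gammas are confined to the beam-on window; fast neutrons arrive within a few
tens of ns of their primary; capture gammas are delayed by neutron
thermalisation, ~12 ns to 10⁶ ns. A per-spill temporal mask of duration
T_mask (events with pulse-relative offset < T_mask are rejected) combined
with an energy window around the capture line (line ± k·σ from the
detector's resolution model) separates capture events from everything else.

`ncgamma` implements this scheme end to end as a tested pipeline:

1. **beam** — pulsed-train timing and primary injection times;
2. **phase_space** — a synthetic, ground-truth-labelled event stream with
   the published energy/time structure (this replaces a full Monte Carlo
   transport calculation);
3. **detector** — material response (photopeak / Compton / escape-peak
   branches, √E resolution scaling, per-band neutron response) and optional
   1 mm thermal-neutron shields, including shield-capture secondaries
   (8.48 / 9.04 MeV for ¹¹³Cd);
4. **discrimination** — mask + window acceptance and TP/FP/TN/FN
   classification against ground truth;
5. **metrics** — sensitivities, the selectivity ratio R_TF = TP : FP with
   ±2σ intervals, and an exhaustive sweep over masks, materials, shields
   and irradiation periods.

## Worked example

Sweep the eight temporal masks for an unshielded CdTe detector viewing a
¹⁰B insert during a 1 µs irradiation (10⁶ primaries):

```python
import ncgamma as ng
from ncgamma.metrics import sweep_grid, find_optimum

sweep = sweep_grid(
    base_config={"nci": "B10", "material": "CdTe", "total_ns": 1e3},
    axes={"mask_ns": ng.MASKS_NS},
    n_primaries=1_000_000, base_seed=1)
print(sweep.table[["mask_ns", "tp", "fp", "sens_tp", "r_tf", "r_tf_ci"]])
best = find_optimum(sweep)
print(f"optimal mask: {best['mask_ns']:g} ns "
      f"(R_TF = {best['r_tf']:.2f} ± {best['r_tf_ci']:.2f})")
```

Output:

```
 mask_ns    tp   fp  sens_tp  r_tf  r_tf_ci
       0 20471 2770  0.05138  7.39   0.2992
      11 20338 1346  0.05105 15.11   0.8505
      30 19939  949  0.05005 21.01    1.396
      40 19693  704  0.04943 27.97    2.146
      50 19449  544  0.04882 35.75    3.108
      60 19207  522  0.04821 36.80    3.264
      70 18990  522  0.04766 36.38    3.228
      80 18810  519  0.04721 36.24    3.225

optimal mask: 60 ns  (R_TF = 36.80 ± 3.26)
```

Reading the table: with no mask, prompt gammas and fast neutrons flood the
478 keV window (R_TF ≈ 7). Masking the 11 ns beam-on window removes the
prompt component; extending the mask to 60 ns progressively removes fast
neutrons, whose arrival is bounded by time of flight. Beyond 60 ns no
mask-sensitive background remains, so longer masks only discard signal —
R_TF peaks at 60 ns and declines. The same sweep for a ¹⁵⁷Gd insert with
an LSO detector at 1 ms peaks at 50 ns: only neutrons above ~1.6 MeV can
reach the 7.94 MeV window, and those arrive earlier.

A thin command-line front end wraps the same stages:

```sh
ncgamma generate --config run.yml --out events.csv
ncgamma respond --config run.yml --events events.csv --out deps.csv
ncgamma discriminate --config run.yml --depositions deps.csv --out classed.csv
ncgamma sweep --config run.yml --out sweep.csv
ncgamma spectrogram --events events.csv --preset photon --out spec.csv
ncgamma report --sweep-csv sweep.csv
```

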