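# photogain

Compartmental modelling of how dendritic morphology determines a neuron's
capacity for **optogenetic gain modulation**.

Neuronal gain — the slope of the input-output (f–I) curve — can be
changed by shifting the balance of excitation and inhibition a neuron
receives across its whole dendritic tree. Dual-opsin photostimulation
(depolarizing channelrhodopsin-2 and hyperpolarizing halorhodopsin,
co-expressed and co-illuminated at a ratio *xNpHR*) provides exactly such
a distributed, balance-shifting drive. This package is for computational
neuroscientists who want to simulate that setting: it generates parametric
dendritic arbors, simulates them as branched passive cables with an active
(Hodgkin–Huxley) soma and Markov-photocycle photocurrents in every
compartment, and quantifies the resulting gain changes.

The core quantities:

- abstract arbors defined by polarity *n_p*, branching *n_b* and stages
  *n_ℓ*, with N_total = n_p · Σ_{k=0}^{n_ℓ−1} n_b^k sections of fixed
  geometry (so total membrane area is conserved while topology varies);
- per-compartment photocurrents i_photo = A·ḡ_photo·ψ(t, φ)·f(V_m) from
  3-, 4- or 6-state opsin photocycles, with expression inversely
  proportional to compartment area;
- IF curves plotting firing rate during photoactivation against the
  background rate of the same run, and the **gain modulation index**

      M = (θ_ChR2 − θ_NpHR) / θ_balanced,    θ = arctan(slope),

  which is 0 when shifting the photocurrent balance merely shifts
  excitability and grows as it rotates the IF curve;
- spike-train statistics (Fano factor, CV of interspike intervals) and
  steady-state attenuation profiles;
- illumination fields with per-pole coverage masks and linear depth
  gradients (scattering-like attenuation per wavelength).

See `docs/methods.md` for the model, its assumptions, and every default.

## Worked example

```python
from photogain.morphology import (MorphologySpec, count_branches,
                                  generate_arbor, total_membrane_area)
from photogain.gain import (make_study_system, drive_sites,
                            calibrate_drive, gain_for_condition)

spec = MorphologySpec(n_p=4, n_b=2, n_levels=5)
print("sections:", count_branches(4, 2, 5))
soma_area, dend_area = total_membrane_area(generate_arbor(spec))
print(f"membrane area: soma {soma_area:.0f} um^2, dendrites {dend_area:.0f} um^2")

arbor, system = make_study_system(spec)
plan = calibrate_drive(system, drive_sites(arbor, seed=42))
print(f"calibrated synaptic weight: {plan.weight*1e3:.2f} nS")

g = gain_for_condition(system, plan, irradiance=0.02, seed=42)
print(f"slope ChR2-dominated: {g.curves['chr2'].slope:.2f}")
print(f"slope balanced:       {g.curves['balanced'].slope:.2f}")
print(f"slope NpHR-dominated: {g.curves['nphr'].slope:.2f}")
print(f"gain modulation index M = {g.M:.2f} (balanced xNpHR = {g.balanced_x:.2f})")
```

Output (about a minute on one CPU):

```
sections: 124
membrane area: soma 314 um^2, dendrites 7791 um^2
calibrated synaptic weight: 3.55 nS
slope ChR2-dominated: 1.02
slope balanced:       0.86
slope NpHR-dominated: 0.25
gain modulation index M = 0.77 (balanced xNpHR = 0.69)
```

Reading it: this multipolar, moderately branched arbor (124 sections,
≈8,000 µm² of dendrite around a 314 µm² soma) relays calibrated synaptic
volleys one-to-one in darkness. At 0.02 mW/mm², ChR2-dominated
illumination (xNpHR = 0.25) leaves the rate transform near the identity,
the balanced ratio (xNpHR ≈ 0.69) likewise, but NpHR-dominated
illumination (xNpHR = 4) *divides* the output — slope 0.25 — rather than
subtracting from it. The angle difference, normalized by the balanced
angle, gives M = 0.77: strong gain modulability. The same protocol on an
unbranched four-chain arbor of equal membrane area, `MorphologySpec(4, 1,
31)`, yields M ≈ 0.02 — its distal photocurrents never reach the soma, so
illumination cannot retune it.

## Command line

```bash
photogain morph generate --np 2 --nb 2 --nl 6 --out arbor.swc
photogain morph stats arbor.swc
photogain simulate --config protocol.yaml --out out/
photogain analyze out/spikes.csv --window 100
photogain recipe validate src/photogain/recipes/abstract_gain_small.yaml
photogain recipe run src/photogain/recipes/abstract_gain_small.yaml --out results/
```

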