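# Methods

## Model overview

`photogain` simulates how the shape of a dendritic arbor determines a
neuron's capacity for *gain modulation* — a change in the slope of its
input-output (IF) curve — when excitatory and inhibitory photocurrents
(ChR2 and NpHR) are distributed over its entire membrane.

The neuron model is a modified ball-and-stick: a single cylindrical soma
(10 µm × 10 µm, ≈314 µm²) carrying standard squid-formalism
Hodgkin–Huxley channels (ḡ_Na = 0.25 S/cm², ḡ_K = 0.1 S/cm²,
g_L = 1.66·10⁻⁴ S/cm², E_L = −60 mV, E_K = −70 mV, E_Na = +50 mV), and a
tree of passive cylindrical sections (50 µm × 0.4 µm, g_pass =
5·10⁻⁵ S/cm², e_pass = −75 mV). Capacitance is read as a *total* value
per compartment (soma 1 pF, section 2 pF) by default; a specific-
capacitance mode (µF/cm²) is available because the printed convention is
ambiguous. Abstract arbors are controlled by three integers — polarity
n_p (primary branches), branching n_b (sister branches per bifurcation)
and stages n_ℓ — giving N_total = n_p·Σ_{k<n_ℓ} n_b^k sections. Section
count is held near 125 across shapes so membrane area (≈8,000 µm²
dendritic) is conserved while topology varies.

## Numerics

Voltage integrates with backward Euler (default dt = 0.025 ms) solved by
tree-ordered (Hines) elimination, O(n) per step; mechanisms advance by
operator splitting. Synapses are single-exponential conductances
(events add weight to g, exponential decay, i = g(V−E)); their
conductances and linear opsin currents enter the implicit step, while
rectifier/pump opsin currents are explicit at the previous voltage
(their magnitudes are far below C/dt, so this is benign). HH gates use
exponential Euler at the new voltage. Photocycle occupancies advance with
exact matrix-exponential propagators, precomputed per distinct irradiance
while light is piecewise-constant; occupancy is therefore conserved to
machine precision for any dt. Compartments sharing an irradiance share
one occupancy track (kinetics are voltage-independent), which makes
whole-field illumination O(1) in opsin state.

Passive steady states (attenuation profiles, two-compartment and cosh
oracles) are computed by a direct linear solve, not time stepping.

## Opsin models

Each opsin is an N-state Markov photocycle; only open states conduct,
the second open state discounted by γ. Light-gated rates scale with a
Hill drive u(φ) = φ/(φ + φ_half) by default (linear option available).
The photocurrent of compartment i is

    i = 10⁻⁵ · (s_i·A_i) · ḡ_photo · ψ(t, φ) · f(V_m)   [nA]

with ψ the conducting-fraction and f the voltage dependence: an inward
rectifier with reversal ≈0 mV for ChR2, a linear driving force with
reversal −400 mV for NpHR (a chloride pump treated as a conductance-like
term), and a `constant` form representing the ideal-pump (current source)
limit. Expression follows the inverse-area rule s_i = G_ref/A_i, so
every compartment produces the same photocurrent at equal irradiance and
voltage; G_ref (default 1 µm² effective collecting area per compartment)
sets overall expression and was chosen so whole-field ChR2-only
activation at 0.02 mW/mm² polarizes the soma by a few millivolts —
comparable to, not dominant over, the background drive, which is the
regime in which gain modulation rather than a firing override occurs.

**The shipped rate constants are plausible defaults, not measurements.**
The source models defer rate constants to fitting workflows; the presets
(3-, 4- and 6-state topologies, YAML) declare every number as editable
configuration. Consequences of this choice are checked structurally
(conservation, monotonicity in irradiance, dark-state absorption,
steady-state agreement with time integration), never against absolute
current amplitudes.

## Superposition and shunting

With pump-type (`constant` f) photocurrents a passive tree is linear, and
the response to light + injection equals the sum of the separate
responses to solver precision; this is the regime behind the observed
linear summation of photocurrent and injection responses. With
conductance-type photocurrents superposition is only approximate: the
ChR2 rectifier's small-signal slope at rest is several-fold its chord
conductance, so at G_ref = 1 µm² illumination adds ~30% to the (very low)
passive membrane conductance and interaction terms reach tens of percent.
That shunting is a real part of the mechanism, and both behaviours are
under test.

## Axial resistivity (study conditions)

`PassiveParams` defaults to 35.4 Ω·cm (a common simulator default; the
value is not constrained by the printed parameters). The gain study
(`StudyConfig`) instead uses 150 Ω·cm, a standard mammalian-dendrite
value. The choice matters: at 35.4 Ω·cm the 0.4-µm sections have
λ ≈ 1.2 mm, so every arbor in the family (depths 0.25–1.55 mm) is
electrotonically compact and morphology barely affects photocurrent
summation at the soma; at 150 Ω·cm, λ ≈ 0.58 mm and deep unbranched
arbors attenuate their distal photocurrents strongly while compact
branched arbors deliver theirs — the distinction the study is about.
The lower value also places the HH soma, loaded by the tree, outside any
repetitive-firing regime.

## The IF-curve drive protocol

With the printed biophysics the soma is a type-II excitable unit: under
constant current it fires once and settles at a depolarized fixed point
(the isolated soma does fire tonically at 60–100 Hz over 0.05–0.2 nA —
the dendritic load removes the limit cycle). Sustained graded rates
therefore come from *transient* drive, consistent with the study design
of presynaptic Poisson input with weights calibrated so that output rate
approximates input rate (loose synaptic democracy).

The protocol: one shared Poisson event train (dead time 15 ms between
volleys) drives 8 excitatory synapses (τ = 2 ms, E = 0 mV) placed on the
sections nearest 100 µm from the soma, balanced round-robin across poles
— the placement rule used for the stellate-like drive, applied uniformly
so every morphology receives an identical drive geometry. The shared
weight is found by bisection to the smallest value relaying 85% of the
arbor's own saturation rate at a 10 Hz probe, then multiplied by a 1.3
safety margin; arbors that cannot relay transients at any weight are
flagged infeasible (deep unbranched paths filter 2-ms transients: the AC
length constant at volley frequencies is ~60 µm). Each run has a
background epoch (drive only, scored 0.4–3.4 s) and an illumination epoch
(3.4–6.8 s, scored after a 400 ms transient skip); one IF point is
(background rate, illuminated rate) of the same frozen drive realization,
rates are swept over 4–20 Hz, and 3 independent realizations per rate are
pooled (9 for the fine-grained pole-coverage comparison) before an
ordinary least-squares line with free intercept is fitted. The free
intercept separates additive excitability shifts from slope (gain)
changes.

The gain index is M = (θ_ChR2 − θ_NpHR)/θ_balanced with θ = arctan(slope)
at xNpHR = 0.25 (ChR2-dominated) and 4 (NpHR-dominated). The balanced
ratio is computed per irradiance by nulling the net steady-state
photocurrent at V = −70 mV; measured balanced slopes fall at 0.86–1.02.

## What the synthetic data emulate — and what they do not

Poisson trains, frozen-noise realizations and site sampling reproduce the
statistical structure of the study's inputs (independent homogeneous
Poisson; quota sampling 80+80 beyond 100 µm; distance-binned
"equidistant" sampling near a target distance). The fixture morphologies
are *synthetic stand-ins*: parametric arbors with the published membrane
areas (60,000 µm² + 1,131 µm² soma pyramidal-like; 30,000 µm²
stellate-like), bipolar/multipolar organization and tapered trunks — not
reconstructions, and with passive+HH biophysics only, not the original
cells' ion-channel complements. Trend tests on abstract arbors therefore
say nothing quantitative about the detailed-cell results; they establish
that the mechanism (morphology-dependent photocurrent summation
controlling IF-slope rotation) operates in the solver.

## Numerical choices and degenerate inputs

Spike detection: upward crossings of 0 mV merged within a 2 ms
refractory window (conventional; results insensitive at default
amplitudes). Event times snap to the dt grid. Zero-duration protocols
return empty results. Fano factor uses consecutive fixed windows and
ddof = 1; CV_ISI requires ≥3 spikes; both return NaN (flagged) when
undefined. The modulation index is NaN when θ_balanced = 0 and warns
when |slope_balanced − 1| > 0.25. Weight calibration reports
infeasibility rather than raising. Multi-point SWC somas collapse to an
equal-lateral-area cylinder with d = L.

## Problem sizes

Default study epochs are 6.8 s simulated per run at dt = 0.025 ms with
~125-compartment arbors; a full three-condition gain estimate is 45 runs
plus ~15 calibration runs. These sizes give rate standard errors near
1 Hz per point, which the pooled fits reduce further; they were chosen as
the smallest runs whose trend comparisons are stable across seeds.

## Known limitations

- Photocycle kinetics are voltage-independent; f(V) carries all voltage
  dependence (the cited 6-state models allow weak voltage coupling).
- Rate constants are representative, not fitted; absolute photocurrent
  amplitudes and the absolute scale of M are therefore not comparable to
  experiments — only orderings and signs are asserted.
- The soma is a single compartment with HH channels only; no axon, no
  Ca²⁺ or adaptation currents, so high-irradiance "tetanic" regimes are
  cruder than in the detailed models.
- Graded illumination uses a linear depth model on path distance, not a
  tissue-optics model.
- Spectral cross-talk (low-level NpHR activation at 475 nm) is not
  modelled; users express it, if desired, through the per-opsin
  irradiance pair.
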