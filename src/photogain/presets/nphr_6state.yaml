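# Halorhodopsin (NpHR), 6-state photocycle (default inhibitory preset).
#
# NpHR is a light-driven inward chloride pump.  It is represented here as a
# conductance-like term with a far-hyperpolarized reversal (-400 mV), so
# over the physiological voltage range the driving force is large and
# nearly constant and the current is outward (hyperpolarizing).  Rate
# constants are plausible defaults for this model family, not measured
# values; override freely.
name: nphr-6state
activation_wavelength_nm: 590
g_max_mS_cm2: 1.0
states: [C1, I1, O1, O2, I2, C2]
dark_state: C1
open_state_weights:
  O1: 1.0
  O2: 0.5
voltage_fn:
  form: linear     # pump treated as conductance with distant reversal
  e_rev_mV: -400.0
light_dependence:
  type: hill
  phi_half_mW_mm2: 0.6
  q: 1.0
transitions:
  - {from: C1, to: I1, rate_ms: 0.4,    light: true}
  - {from: I1, to: O1, rate_ms: 1.5}
  - {from: O1, to: C1, rate_ms: 0.1}
  - {from: O1, to: O2, rate_ms: 0.04,   light: true}
  - {from: O2, to: O1, rate_ms: 0.008}
  - {from: O2, to: C2, rate_ms: 0.012}
  - {from: C2, to: I2, rate_ms: 0.1,    light: true}
  - {from: I2, to: O2, rate_ms: 0.8}
  - {from: C2, to: C1, rate_ms: 0.0005}
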