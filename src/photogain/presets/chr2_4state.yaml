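# Channelrhodopsin-2, 4-state photocycle: two closed / two open states
# with light-gated interconversion of the open states.  Plausible default
# constants, declared as configuration.
name: chr2-4state
activation_wavelength_nm: 475
g_max_mS_cm2: 1.0
states: [C1, O1, O2, C2]
dark_state: C1
open_state_weights:
  O1: 1.0
  O2: 0.5
voltage_fn:
  form: rectifier
  e_rev_mV: 0.0
  u_mV: 40.0
light_dependence:
  type: hill
  phi_half_mW_mm2: 0.5
  q: 1.0
transitions:
  - {from: C1, to: O1, rate_ms: 0.5,   light: true}
  - {from: O1, to: C1, rate_ms: 0.12}
  - {from: O1, to: O2, rate_ms: 0.05,  light: true}
  - {from: O2, to: O1, rate_ms: 0.008}
  - {from: O2, to: C2, rate_ms: 0.01}
  - {from: C2, to: O2, rate_ms: 0.1,   light: true}
  - {from: C2, to: C1, rate_ms: 0.0004}
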