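# Channelrhodopsin-2, minimal 3-state photocycle (closed -> open ->
# desensitized -> closed).  Uses the *linear* light-dependence option, so
# light-gated rates scale proportionally with irradiance.  Plausible
# default constants, declared as configuration.
name: chr2-3state
activation_wavelength_nm: 475
g_max_mS_cm2: 1.0
states: [C, O, D]
dark_state: C
open_state_weights:
  O: 1.0
voltage_fn:
  form: linear
  e_rev_mV: 0.0
light_dependence:
  type: linear
  phi_ref_mW_mm2: 1.0
transitions:
  - {from: C, to: O, rate_ms: 0.5,    light: true}
  - {from: O, to: D, rate_ms: 0.1}
  - {from: D, to: C, rate_ms: 0.004}
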