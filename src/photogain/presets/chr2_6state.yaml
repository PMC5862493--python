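# Channelrhodopsin-2, 6-state photocycle (default excitatory preset).
#
# Topology: two closed states (C1 dark-adapted, C2 light-adapted), two
# short-lived excited intermediates (I1, I2) and two open states (O1, O2);
# O2 conducts at a fraction gamma of O1.  Rate constants are plausible
# defaults for this model family, declared here as editable configuration
# rather than measured values; every number can be overridden.
#
# Units: rates ms^-1 (light-gated rates are the value at full drive u = 1),
# g_max mS/cm^2, irradiance mW/mm^2, voltages mV.
name: chr2-6state
activation_wavelength_nm: 475
g_max_mS_cm2: 1.0
states: [C1, I1, O1, O2, I2, C2]
dark_state: C1
open_state_weights:
  O1: 1.0
  O2: 0.6          # gamma: relative conductance of the second open state
voltage_fn:
  form: rectifier  # inward-rectifying ChR2 I-V, reversal near 0 mV
  e_rev_mV: 0.0
  u_mV: 40.0
light_dependence:
  type: hill
  phi_half_mW_mm2: 0.5
  q: 1.0
transitions:
  - {from: C1, to: I1, rate_ms: 0.5,    light: true}   # photon absorption
  - {from: I1, to: O1, rate_ms: 2.0}                   # fast channel opening
  - {from: O1, to: C1, rate_ms: 0.12}                  # dark closure
  - {from: O1, to: O2, rate_ms: 0.05,   light: true}   # light-adapted branch
  - {from: O2, to: O1, rate_ms: 0.008}
  - {from: O2, to: C2, rate_ms: 0.01}                  # closure (adapted)
  - {from: C2, to: I2, rate_ms: 0.12,   light: true}   # re-excitation
  - {from: I2, to: O2, rate_ms: 1.0}
  - {from: C2, to: C1, rate_ms: 0.0004}                # slow dark recovery
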