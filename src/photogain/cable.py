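"""Branched-cable compartmental simulator.

The membrane system is a soma-rooted tree of cylindrical compartments with
passive leak everywhere, standard Hodgkin-Huxley sodium/potassium channels
at the soma, single-exponential conductance synapses, constant current
injections, and per-compartment photocurrents from decorated opsins under
a configurable illumination field.

Voltage is integrated with a backward-Euler step solved by tree-ordered
(Hines) elimination; mechanism states advance by operator splitting (see
:mod:`photogain._kernel`).  Everything is deterministic given the protocol
and dt; stochasticity enters only through presynaptic event times, which
are generated upstream with explicit seeds.

Units: mV, ms, nA, uS, nF, um; specific quantities in S/cm^2, uF/cm^2,
Ohm*cm, mW/mm^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import _kernel
from ._kernel import F_CONSTANT, F_LINEAR, F_RECTIFIER, hh_steady_gates, run_kernel
from .morphology import SOMA_ID, Arbor
from .opsins import OpsinPlacement, PhotocycleModel, propagator, rate_matrix

__all__ = [
    "PassiveParams", "HHParams", "SynapseSpec", "CurrentInjection",
    "OpsinLight", "IlluminationField", "Protocol", "SimResult",
    "CableSystem", "NumericalError", "build_system", "run", "step",
    "detect_spikes", "make_illumination", "partial_mask",
    "steady_state_passive", "resting_potential",
    "calibrate_synaptic_weights", "CalibrationResult",
]

_FORM_CODES = {"linear": F_LINEAR, "rectifier": F_RECTIFIER,
               "constant": F_CONSTANT}


class NumericalError(RuntimeError):
    """Integration produced a non-finite voltage."""


@dataclass(frozen=True)
class PassiveParams:
    """Passive membrane and axial parameters.

    ``capacitance_mode='total'`` reads compartment capacitance as a total
    per-section value in pF (soma 1 pF, dendritic section 2 pF by default);
    ``'specific'`` uses ``c_specific_uF_cm2`` times membrane area instead.
    """

    g_pass: float = 5e-5          # S/cm^2
    e_pass: float = -75.0         # mV
    axial_resistivity: float = 35.4   # Ohm*cm (assumed default, not measured)
    capacitance_mode: str = "total"
    c_soma_pF: float = 1.0
    c_section_pF: float = 2.0
    c_specific_uF_cm2: float = 1.0

    def __post_init__(self):
        if self.g_pass <= 0 or self.axial_resistivity <= 0:
            raise ValueError("conductance and resistivity must be > 0")
        if self.capacitance_mode not in ("total", "specific"):
            raise ValueError("capacitance_mode must be 'total' or 'specific'")
        if min(self.c_soma_pF, self.c_section_pF,
               self.c_specific_uF_cm2) <= 0:
            raise ValueError("capacitances must be > 0")


@dataclass(frozen=True)
class HHParams:
    """Squid-formalism Hodgkin-Huxley channels (soma only)."""

    gnabar: float = 0.25      # S/cm^2
    gkbar: float = 0.1
    gl: float = 0.000166
    el: float = -60.0         # mV
    ek: float = -70.0
    ena: float = 50.0

    def __post_init__(self):
        if min(self.gnabar, self.gkbar, self.gl) < 0:
            raise ValueError("conductances must be >= 0")


@dataclass
class SynapseSpec:
    """Single-exponential conductance synapse.

    An event instantaneously increments the conductance by ``weight`` (uS);
    it then decays with time constant ``tau``; the synaptic current is
    g * (V - reversal).
    """

    section_id: int
    weight: float              # uS
    tau: float = 0.1           # ms
    reversal: float = 0.0      # mV (0 excitatory, -80 inhibitory)
    event_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        self.event_times = np.asarray(self.event_times, float)
        if self.event_times.size and np.any(np.diff(self.event_times) < 0):
            raise ValueError("event times must be sorted")


@dataclass(frozen=True)
class CurrentInjection:
    section_id: int
    amplitude: float           # nA
    t_start: float = 0.0       # ms
    t_stop: float = float("inf")


@dataclass
class OpsinLight:
    """Illumination of one opsin: nominal irradiance over a coverage mask.

    ``coverage`` is a set of section ids (may include the soma id); None
    means full coverage including the soma.  ``gradient`` in [0, 1] scales
    irradiance linearly with normalized depth: 0 = uniform, 1 = nominal at
    the illuminated surface falling to zero at the deepest covered
    compartment.  ``light_from='distal'`` treats the most distal covered
    compartment as the illuminated surface (light arriving from outside
    the tissue), ``'soma'`` reverses the axis.
    """

    irradiance: float
    t_on: float = 0.0
    t_off: float = float("inf")
    coverage: Optional[Sequence[int]] = None
    gradient: float = 0.0
    light_from: str = "distal"

    def __post_init__(self):
        if self.irradiance < 0:
            raise ValueError("irradiance must be >= 0")
        if not 0.0 <= self.gradient <= 1.0:
            raise ValueError("gradient must lie in [0, 1]")
        if self.light_from not in ("distal", "soma"):
            raise ValueError("light_from must be 'distal' or 'soma'")


@dataclass
class IlluminationField:
    """Per-opsin illumination, keyed by opsin model name."""

    lights: Dict[str, OpsinLight] = field(default_factory=dict)


@dataclass
class Protocol:
    injections: List[CurrentInjection] = field(default_factory=list)
    synapses: List[SynapseSpec] = field(default_factory=list)
    illumination: Optional[IlluminationField] = None


@dataclass
class SimResult:
    t: np.ndarray                       # ms
    dt: float
    voltage: Dict[Union[int, str], np.ndarray]    # mV per recorded site
    photocurrent: Dict[str, np.ndarray]           # nA, outward positive
    spike_times: np.ndarray                       # ms, soma
    meta: dict = field(default_factory=dict)

    @property
    def soma_v(self) -> np.ndarray:
        return self.voltage["soma"]


# ---------------------------------------------------------------------------
# System construction
# ---------------------------------------------------------------------------

class CableSystem:
    """Flattened compartmental representation of an arbor plus mechanisms."""

    def __init__(self, arbor: Arbor, passive: PassiveParams,
                 hh_soma: Optional[HHParams],
                 opsins: List[Tuple[PhotocycleModel, OpsinPlacement]],
                 nseg: int):
        if nseg < 1:
            raise ValueError("nseg must be >= 1")
        self.arbor = arbor
        self.passive = passive
        self.hh = hh_soma
        self.nseg = nseg
        ra = passive.axial_resistivity

        ids = [SOMA_ID] + [s.id for s in arbor.sections]
        self._sec_first_comp: Dict[int, int] = {}
        self._sec_last_comp: Dict[int, int] = {}

        n = 1 + nseg * len(arbor.sections)
        parent = np.full(n, -1, np.int64)
        length = np.empty(n)
        diam = np.empty(n)
        pole = np.full(n, -1, np.int64)
        path_mid = np.zeros(n)

        length[0] = arbor.soma.length
        diam[0] = arbor.soma.diameter
        self._sec_first_comp[SOMA_ID] = 0
        self._sec_last_comp[SOMA_ID] = 0

        c = 1
        for s in arbor.sections:
            lc = s.length / nseg
            for k in range(nseg):
                if k == 0:
                    parent[c] = self._sec_last_comp[s.parent_id]
                else:
                    parent[c] = c - 1
                length[c] = lc
                diam[c] = s.diameter
                pole[c] = s.pole_index
                path_mid[c] = s.path_distance_to_soma + (k + 0.5) * lc
                if k == 0:
                    self._sec_first_comp[s.id] = c
                c += 1
            self._sec_last_comp[s.id] = c - 1
        if np.any(parent[1:] >= np.arange(1, n)):
            raise ValueError("sections are not in topological order")

        area_um2 = math.pi * diam * length
        area_cm2 = area_um2 * 1e-8
        self.n = n
        self.parent = parent
        self.length = length
        self.diam = diam
        self.pole = pole
        self.path_mid = path_mid
        self.area_um2 = area_um2

        # axial conductance to parent (uS): half-cylinder resistances in Ohm
        g_ax = np.zeros(n)
        for i in range(1, n):
            p = parent[i]
            r_half = 0.0
            for j in (i, p):
                radius_cm = diam[j] / 2 * 1e-4
                l_cm = length[j] / 2 * 1e-4
                r_half += ra * l_cm / (math.pi * radius_cm ** 2)
            g_ax[i] = 1e6 / r_half
        self.g_ax = g_ax

        self.g_pas = passive.g_pass * area_cm2 * 1e6  # uS
        self.e_pas = passive.e_pass
        if passive.capacitance_mode == "total":
            cap = np.empty(n)
            cap[0] = passive.c_soma_pF * 1e-3
            cap[1:] = passive.c_section_pF / nseg * 1e-3
        else:
            cap = passive.c_specific_uF_cm2 * area_cm2 * 1e3  # nF
        self.cap = cap

        if hh_soma is not None:
            soma_cm2 = area_cm2[0]
            self._hh_abs = (hh_soma.gnabar * soma_cm2 * 1e6,
                            hh_soma.gkbar * soma_cm2 * 1e6,
                            hh_soma.gl * soma_cm2 * 1e6)
        else:
            self._hh_abs = (0.0, 0.0, 0.0)

        # opsins: per-compartment current prefactor (nA per unit psi*f)
        self.opsins: List[Tuple[PhotocycleModel, np.ndarray]] = []
        for model, placement in opsins:
            scale_by_id = dict(zip(placement.section_ids.tolist(),
                                   placement.scale.tolist()))
            gpref = np.zeros(n)
            for sid in ids:
                if sid not in scale_by_id:
                    continue
                first = self._sec_first_comp[sid]
                last = self._sec_last_comp[sid]
                for ci in range(first, last + 1):
                    gpref[ci] = (1e-5 * model.g_max * scale_by_id[sid]
                                 * area_um2[ci])
            self.opsins.append((model, gpref))

        self.reset()

    # -- state ---------------------------------------------------------------

    def reset(self, v0: Optional[float] = None) -> None:
        """Reset voltages, gates and photocycles to a quiescent state."""
        v_init = self.e_pas if v0 is None else v0
        self.v = np.full(self.n, float(v_init))
        self.gates = hh_steady_gates(float(v_init))
        self._occ_dark = [m.dark_occupancy().occupancy for m, _ in self.opsins]

    # -- lookups ---------------------------------------------------------------

    def comp_of(self, site: Union[int, str], loc: str = "distal") -> int:
        if site == "soma":
            return 0
        try:
            first = self._sec_first_comp[int(site)]
            last = self._sec_last_comp[int(site)]
        except KeyError:
            raise KeyError(f"unknown section id {site!r}") from None
        if loc == "distal":
            return last
        if loc == "proximal":
            return first
        raise ValueError("loc must be 'distal' or 'proximal'")

    def section_comps(self, section_id: int) -> range:
        return range(self._sec_first_comp[section_id],
                     self._sec_last_comp[section_id] + 1)

    @property
    def opsin_names(self) -> List[str]:
        return [m.name for m, _ in self.opsins]


def build_system(arbor: Arbor,
                 passive: Optional[PassiveParams] = None,
                 hh_soma: Optional[HHParams] = None,
                 opsin_placements: Optional[
                     List[Tuple[PhotocycleModel, OpsinPlacement]]] = None,
                 nseg: int = 1) -> CableSystem:
    """Assemble a simulatable system from an arbor and mechanism configs."""
    return CableSystem(arbor, passive or PassiveParams(), hh_soma,
                       opsin_placements or [], nseg)


# ---------------------------------------------------------------------------
# Illumination geometry
# ---------------------------------------------------------------------------

def partial_mask(arbor: Arbor, illuminated_poles: Sequence[int],
                 include_soma: bool = True) -> List[int]:
    """Coverage mask of all sections in the listed pole subtrees."""
    poles = set(int(p) for p in illuminated_poles)
    known = set(s.pole_index for s in arbor.sections)
    unknown = poles - known
    if unknown:
        raise KeyError(f"unknown pole indices {sorted(unknown)}")
    mask = [s.id for s in arbor.sections if s.pole_index in poles]
    if include_soma and poles:
        mask = [SOMA_ID] + mask
    return mask


def make_illumination(arbor: Arbor, field_: IlluminationField
                      ) -> Dict[str, Dict[int, float]]:
    """Resolve an illumination field to per-section irradiances.

    For each opsin, covered sections receive
    ``irr * (1 - gradient * depth_norm)`` with the depth coordinate taken
    as path distance of the section midpoint from the soma, normalized over
    the covered set from the illuminated surface (depth_norm 0) to the
    deepest covered compartment (depth_norm 1).  Uncovered sections get 0.
    """
    out: Dict[str, Dict[int, float]] = {}
    all_ids = [SOMA_ID] + [s.id for s in arbor.sections]
    for name, light in field_.lights.items():
        cov = list(light.coverage) if light.coverage is not None else all_ids
        for sid in cov:
            arbor.section(sid)  # existence check
        dist = {sid: (0.0 if sid == SOMA_ID
                      else arbor.section(sid).mid_distance) for sid in cov}
        phi = {sid: 0.0 for sid in all_ids}
        if cov:
            d = np.array([dist[s] for s in cov])
            d_lo, d_hi = d.min(), d.max()
            span = d_hi - d_lo
            for sid in cov:
                if span == 0.0:
                    depth_norm = 0.0
                elif light.light_from == "distal":
                    depth_norm = (d_hi - dist[sid]) / span
                else:
                    depth_norm = (dist[sid] - d_lo) / span
                phi[sid] = light.irradiance * (1.0 - light.gradient * depth_norm)
        out[name] = phi
    return out


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

_EMPTY_F = np.empty(0)
_EMPTY_I = np.empty(0, np.int64)


def _opsin_arrays(system: CableSystem, protocol: Protocol, dt: float,
                  n_steps: int):
    """Precompute occupancy tracks and propagators for each opsin."""
    n_ops = len(system.opsins)
    if n_ops == 0:
        return (0, np.zeros((1, 1, 1)), np.zeros((1, 1, 1, 1)),
                np.zeros((1, 1, 1)),
                np.zeros((1, 1)), np.full((1, system.n), -1, np.int64),
                np.zeros((1, system.n)), np.zeros(1, np.int64),
                np.zeros(1), np.ones(1),
                np.zeros(1, np.int64), np.zeros(1, np.int64))

    phi_by_name: Dict[str, Dict[int, float]] = {}
    lights: Dict[str, OpsinLight] = {}
    if protocol.illumination is not None:
        phi_by_name = make_illumination(system.arbor, protocol.illumination)
        lights = protocol.illumination.lights
        unknown = set(lights) - set(system.opsin_names)
        if unknown:
            raise KeyError(f"illumination names {sorted(unknown)} do not "
                           f"match decorated opsins {system.opsin_names}")

    S = max(m.n_states for m, _ in system.opsins)
    phi_comp = np.zeros((n_ops, system.n))
    for o, (model, gpref) in enumerate(system.opsins):
        phis = phi_by_name.get(model.name)
        if phis is None:
            continue
        for sid, phi in phis.items():
            for ci in system.section_comps(sid):
                phi_comp[o, ci] = phi

    tracks = []
    K = 1
    for o in range(n_ops):
        uniq, inv = np.unique(np.round(phi_comp[o], 12), return_inverse=True)
        tracks.append((uniq, inv))
        K = max(K, len(uniq))

    occ = np.zeros((n_ops, K, S))
    prop_on = np.zeros((n_ops, K, S, S))
    prop_off = np.zeros((n_ops, S, S))
    wts = np.zeros((n_ops, S))
    track = np.full((n_ops, system.n), -1, np.int64)
    gpref_arr = np.zeros((n_ops, system.n))
    f_form = np.zeros(n_ops, np.int64)
    f_pa = np.zeros(n_ops)
    f_pb = np.ones(n_ops)
    l_on = np.zeros(n_ops, np.int64)
    l_off = np.zeros(n_ops, np.int64)

    for o, (model, gpref) in enumerate(system.opsins):
        s = model.n_states
        uniq, inv = tracks[o]
        dark = model.dark_occupancy().occupancy
        for k, phi in enumerate(uniq):
            occ[o, k, :s] = dark
            prop_on[o, k, :s, :s] = propagator(rate_matrix(model, float(phi)),
                                               dt)
            for pad in range(s, S):
                prop_on[o, k, pad, pad] = 1.0
        for k in range(len(uniq), K):
            prop_on[o, k] = np.eye(S)
        prop_off[o, :s, :s] = propagator(rate_matrix(model, 0.0), dt)
        for pad in range(s, S):
            prop_off[o, pad, pad] = 1.0
        wts[o, :s] = model.open_state_weights
        track[o] = inv
        gpref_arr[o] = gpref
        form = model.voltage_fn["form"]
        f_form[o] = _FORM_CODES[form]
        if form == "linear":
            f_pa[o] = float(model.voltage_fn["e_rev_mV"])
        elif form == "rectifier":
            f_pa[o] = float(model.voltage_fn["e_rev_mV"])
            f_pb[o] = float(model.voltage_fn.get("u_mV", 40.0))
        else:
            f_pa[o] = float(model.voltage_fn["drive_mV"])
        light = lights.get(model.name)
        if light is None:
            l_on[o] = n_steps + 1
            l_off[o] = n_steps + 1
        else:
            l_on[o] = int(round(light.t_on / dt))
            l_off[o] = (n_steps if math.isinf(light.t_off)
                        else int(round(light.t_off / dt)))
    return (n_ops, occ, prop_on, prop_off, wts, track, gpref_arr,
            f_form, f_pa, f_pb, l_on, l_off)


def _synapse_arrays(system: CableSystem, synapses: List[SynapseSpec],
                    dt: float, n_steps: int):
    ns = len(synapses)
    syn_comp = np.zeros(ns, np.int64)
    syn_decay = np.ones(ns)
    syn_e = np.zeros(ns)
    syn_w = np.zeros(ns)
    steps: List[Tuple[int, int]] = []
    for j, syn in enumerate(synapses):
        syn_comp[j] = system.comp_of(syn.section_id)
        syn_decay[j] = math.exp(-dt / syn.tau)
        syn_e[j] = syn.reversal
        syn_w[j] = syn.weight
        for t in syn.event_times:
            it = int(round(t / dt))
            if 0 <= it < n_steps:
                steps.append((it, j))
    steps.sort()
    ev_step = np.array([s for s, _ in steps], np.int64)
    ev_syn = np.array([j for _, j in steps], np.int64)
    return syn_comp, syn_decay, syn_e, syn_w, ev_step, ev_syn


def run(system: CableSystem, protocol: Protocol, duration: float,
        record_sites: Sequence[Union[int, str]] = ("soma",),
        dt: float = 0.025, v_init: Optional[float] = None,
        spike_threshold: float = 0.0, refractory_ms: float = 2.0,
        meta: Optional[dict] = None) -> SimResult:
    """Simulate ``duration`` ms of the protocol and return recorded traces.

    Deterministic: identical system, protocol and dt give identical output.
    The soma is always recorded; spike times are detected on its trace by
    upward threshold crossing with a refractory merge window.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    sites = list(record_sites)
    if "soma" not in sites:
        sites = ["soma"] + sites
    rec_idx = np.array([system.comp_of(s) for s in sites], np.int64)

    n_steps = int(round(duration / dt))
    names = system.opsin_names
    if n_steps <= 0:
        return SimResult(t=np.empty(0), dt=dt,
                         voltage={s: np.empty(0) for s in sites},
                         photocurrent={nm: np.empty(0) for nm in names},
                         spike_times=np.empty(0), meta=meta or {})

    system.reset(v_init)
    v = system.v
    gates = system.gates
    gna, gk, gl = system._hh_abs
    hh = system.hh

    (n_ops, occ, prop_on, prop_off, wts, track, gpref, f_form, f_pa, f_pb,
     l_on, l_off) = _opsin_arrays(system, protocol, dt, n_steps)

    n_inj = len(protocol.injections)
    inj_comp = np.zeros(n_inj, np.int64)
    inj_amp = np.zeros(n_inj)
    inj_on = np.zeros(n_inj, np.int64)
    inj_off = np.zeros(n_inj, np.int64)
    for j, inj in enumerate(protocol.injections):
        inj_comp[j] = system.comp_of(inj.section_id)
        inj_amp[j] = inj.amplitude
        inj_on[j] = int(round(inj.t_start / dt))
        inj_off[j] = (n_steps if math.isinf(inj.t_stop)
                      else int(round(inj.t_stop / dt)))

    syn_comp, syn_decay, syn_e, syn_w, ev_step, ev_syn = _synapse_arrays(
        system, protocol.synapses, dt, n_steps)
    syn_g = np.zeros(len(protocol.synapses))

    rec_v = np.empty((n_steps + 1, len(sites)))
    rec_iph = np.zeros((n_steps + 1, max(n_ops, 1)))

    status = run_kernel(
        n_steps, dt, system.parent, system.g_ax, system.cap, system.g_pas,
        system.e_pas, v,
        hh is not None, gna, gk, gl,
        hh.ena if hh else 0.0, hh.ek if hh else 0.0, hh.el if hh else 0.0,
        gates,
        n_ops, occ, prop_on, prop_off, wts, track, gpref,
        f_form, f_pa, f_pb, l_on, l_off,
        inj_comp, inj_amp, inj_on, inj_off,
        syn_comp, syn_decay, syn_e, syn_w, syn_g,
        ev_step, ev_syn, rec_idx, rec_v, rec_iph)
    if status != _kernel.STATUS_OK:
        raise NumericalError(
            f"non-finite voltage near t = {(status - 1) * dt:.3f} ms")

    t = np.arange(n_steps + 1) * dt
    voltage = {s: rec_v[:, i].copy() for i, s in enumerate(sites)}
    photocurrent = {nm: rec_iph[:, o].copy() for o, nm in enumerate(names)}
    spikes = detect_spikes(voltage["soma"], dt, spike_threshold, refractory_ms)
    return SimResult(t=t, dt=dt, voltage=voltage, photocurrent=photocurrent,
                     spike_times=spikes, meta=meta or {})


def step(system: CableSystem, dt: float,
         injections: Optional[Dict[int, float]] = None) -> np.ndarray:
    """Advance the system's persistent state by a single implicit step.

    ``injections`` maps compartment index -> constant current (nA) applied
    during the step.  Opsins are advanced in darkness.  Returns the new
    voltage vector (a view of the system state).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    inj = injections or {}
    inj_comp = np.array(list(inj.keys()), np.int64)
    inj_amp = np.array(list(inj.values()), float)
    inj_on = np.zeros(len(inj), np.int64)
    inj_off = np.ones(len(inj), np.int64)
    gna, gk, gl = system._hh_abs
    hh = system.hh

    (n_ops, occ, prop_on, prop_off, wts, track, gpref, f_form, f_pa, f_pb,
     l_on, l_off) = _opsin_arrays(system, Protocol(), dt, 1)

    rec_idx = np.zeros(1, np.int64)
    rec_v = np.empty((2, 1))
    rec_iph = np.zeros((2, max(n_ops, 1)))
    status = run_kernel(
        1, dt, system.parent, system.g_ax, system.cap, system.g_pas,
        system.e_pas, system.v,
        hh is not None, gna, gk, gl,
        hh.ena if hh else 0.0, hh.ek if hh else 0.0, hh.el if hh else 0.0,
        system.gates,
        n_ops, occ, prop_on, prop_off, wts, track, gpref,
        f_form, f_pa, f_pb, l_on, l_off,
        inj_comp, inj_amp, inj_on, inj_off,
        _EMPTY_I, _EMPTY_F, _EMPTY_F, _EMPTY_F, _EMPTY_F,
        _EMPTY_I, _EMPTY_I, rec_idx, rec_v, rec_iph)
    if status != _kernel.STATUS_OK:
        raise NumericalError("non-finite voltage within a single step")
    return system.v


def detect_spikes(voltage_trace: np.ndarray, dt: float,
                  threshold_mV: float = 0.0,
                  refractory_ms: float = 2.0) -> np.ndarray:
    """Upward threshold crossings, merged within the refractory window."""
    v = np.asarray(voltage_trace, float)
    if v.size < 2:
        return np.empty(0)
    crossings = np.nonzero((v[:-1] < threshold_mV)
                           & (v[1:] >= threshold_mV))[0] + 1
    if crossings.size == 0:
        return np.empty(0)
    times = crossings * dt
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory_ms:
            kept.append(t)
    return np.asarray(kept)


# ---------------------------------------------------------------------------
# Passive steady state (direct linear solve)
# ---------------------------------------------------------------------------

def _passive_matrix(system: CableSystem) -> Tuple[np.ndarray, np.ndarray]:
    n = system.n
    G = np.zeros((n, n))
    b = system.g_pas * system.e_pas
    G[np.diag_indices(n)] += system.g_pas
    for i in range(1, n):
        p = system.parent[i]
        g = system.g_ax[i]
        G[i, i] += g
        G[p, p] += g
        G[i, p] -= g
        G[p, i] -= g
    return G, b.copy()


def steady_state_passive(system: CableSystem,
                         injections: Optional[Dict[Union[int, str], float]]
                         = None) -> np.ndarray:
    """Exact steady-state voltage of a passive system under constant drive.

    ``injections`` maps section id (or 'soma') -> nA injected at the
    section's distal compartment.  Raises if active soma channels are
    present (the steady state would not be a linear solve).
    """
    if system.hh is not None:
        raise ValueError("steady_state_passive requires a passive system "
                         "(build with hh_soma=None)")
    G, b = _passive_matrix(system)
    for site, amp in (injections or {}).items():
        b[system.comp_of(site)] += amp
    return np.linalg.solve(G, b)


def resting_potential(system: CableSystem, settle_ms: float = 300.0,
                      dt: float = 0.025) -> float:
    """Soma membrane potential after settling with no stimulus."""
    res = run(system, Protocol(), settle_ms, dt=dt)
    return float(res.soma_v[-1])


# ---------------------------------------------------------------------------
# Synaptic weight calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    weight: Optional[float]
    rate: Optional[float]
    feasible: bool
    message: str = ""
    n_evals: int = 0


def calibrate_synaptic_weights(rate_probe: Callable[[float], float],
                               target_rate_hz: float,
                               bracket: Tuple[float, float] = (1e-5, 0.02),
                               tol_hz: float = 1.0,
                               max_iter: int = 50,
                               max_expand: int = 8) -> CalibrationResult:
    """Find a shared synaptic weight whose output rate matches the target.

    Enforces a loose form of synaptic democracy: one scalar weight across
    all sites such that |output - target| <= tol at the probe drive.
    ``rate_probe(weight) -> Hz`` must be monotone non-decreasing over the
    bracket.  When no bracket with r(lo) < target < r(hi) can be
    established (after geometric expansion of the upper edge), the result
    is flagged infeasible rather than raising - some arbor configurations
    simply cannot produce a transient somatic response.
    """
    lo, hi = bracket
    if not (0 < lo < hi):
        raise ValueError("bracket must satisfy 0 < lo < hi")
    evals = 0

    def probe(w):
        nonlocal evals
        evals += 1
        return float(rate_probe(w))

    r_lo = probe(lo)
    if abs(r_lo - target_rate_hz) <= tol_hz:
        return CalibrationResult(lo, r_lo, True, "target met at lower edge",
                                 evals)
    if r_lo > target_rate_hz:
        return CalibrationResult(None, r_lo, False,
                                 "rate already above target at lower edge",
                                 evals)
    r_hi = probe(hi)
    expand = 0
    while r_hi < target_rate_hz and expand < max_expand:
        lo, r_lo = hi, r_hi
        hi *= 2.0
        r_hi = probe(hi)
        expand += 1
    if abs(r_hi - target_rate_hz) <= tol_hz:
        return CalibrationResult(hi, r_hi, True, "target met at upper edge",
                                 evals)
    if r_hi < target_rate_hz:
        return CalibrationResult(
            None, r_hi, False,
            "no bracket: response stays below target (infeasible)", evals)
    for _ in range(max_iter):
        mid = math.sqrt(lo * hi)
        r_mid = probe(mid)
        if abs(r_mid - target_rate_hz) <= tol_hz:
            return CalibrationResult(mid, r_mid, True, "converged", evals)
        if r_mid < target_rate_hz:
            lo = mid
        else:
            hi = mid
    return CalibrationResult(mid, r_mid, False,
                             "bisection did not reach tolerance", evals)
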