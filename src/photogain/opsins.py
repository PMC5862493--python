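"""Markov photocycle models of light-gated opsins (ChR2, NpHR).

An opsin is an N-state continuous-time Markov chain whose light-gated
transition rates scale with irradiance.  Only open states conduct; the
photocurrent of a compartment is

    i_photo = scale * g_max * psi(t, phi) * f(V_m)

where ``psi`` is the conductance-weighted open-state occupancy (the second
open state is discounted by a ratio gamma <= 1), ``g_max`` the maximal
specific conductance, and ``f`` a voltage-dependence term.  Three
voltage-dependence forms are supported:

- ``linear``:    f = V - E_rev            (ohmic channel)
- ``rectifier``: f = U * (1 - exp(-(V - E_rev)/U))   (inward-rectifying,
  ChR2-like: the photocurrent grows super-linearly with hyperpolarization)
- ``constant``:  f = drive_mV             (ideal current source; the limit
  appropriate for ion pumps whose turnover is nearly voltage independent)

Rate constants are not hard-coded: presets for 3-, 4- and 6-state
topologies ship as editable YAML files with literature-plausible defaults
(see ``presets/``), and every constant can be overridden.  Light dependence
of gated rates is Hill-type by default (``u = phi^q / (phi^q + phi_half^q)``)
with a linear option (``u = phi / phi_ref``).

Units: rates ms^-1, conductance mS/cm^2, irradiance mW/mm^2, voltage mV,
current nA.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import scipy.linalg
import yaml

from .morphology import Arbor, SOMA_ID

__all__ = [
    "Transition",
    "PhotocycleModel",
    "OpsinState",
    "OpsinPlacement",
    "load_preset",
    "available_presets",
    "rate_matrix",
    "step_occupancy",
    "steady_state_occupancy",
    "photocurrent",
    "voltage_factor",
    "decorate_inverse_area",
    "xnphr_condition",
]

#: converts (g_max [mS/cm^2] * area [um^2] * psi * f [mV]) to nA
_CURRENT_UNIT = 1e-5


@dataclass(frozen=True)
class Transition:
    source: int
    target: int
    rate: float  # ms^-1 (at full light drive u = 1 when light-gated)
    light_gated: bool = False

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError(f"negative rate {self.rate}")


@dataclass
class PhotocycleModel:
    """N-state photocycle with light-dependent rates."""

    name: str
    state_names: List[str]
    dark_state_index: int
    open_state_weights: np.ndarray  # weight per state; zero when non-conducting
    transitions: List[Transition]
    g_max: float  # mS/cm^2
    voltage_fn: Dict[str, float]  # {"form": ..., parameters...}
    light_dependence: Dict[str, float]  # {"type": "hill"|"linear", ...}
    activation_wavelength_nm: float = float("nan")

    def __post_init__(self):
        self.open_state_weights = np.asarray(self.open_state_weights, float)
        n = len(self.state_names)
        if n < 3:
            raise ValueError("photocycle needs at least 3 states")
        if self.open_state_weights.shape != (n,):
            raise ValueError("open_state_weights length mismatch")
        if (self.open_state_weights < 0).any() or \
                not (self.open_state_weights > 0).any():
            raise ValueError("need non-negative weights with >= 1 positive")
        for tr in self.transitions:
            if not (0 <= tr.source < n and 0 <= tr.target < n):
                raise ValueError("transition state index out of range")

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def light_drive(self, irradiance: float) -> float:
        """Dimensionless activation u(phi) in [0, inf)."""
        if irradiance < 0:
            raise ValueError("irradiance must be >= 0")
        dep = self.light_dependence
        kind = dep.get("type", "hill")
        if kind == "hill":
            q = float(dep.get("q", 1.0))
            half = float(dep["phi_half_mW_mm2"])
            if irradiance == 0.0:
                return 0.0
            p = irradiance ** q
            return p / (p + half ** q)
        if kind == "linear":
            return irradiance / float(dep.get("phi_ref_mW_mm2", 1.0))
        raise ValueError(f"unknown light dependence {kind!r}")

    def dark_occupancy(self) -> "OpsinState":
        occ = np.zeros(self.n_states)
        occ[self.dark_state_index] = 1.0
        return OpsinState(occ)

    @classmethod
    def from_dict(cls, cfg: dict) -> "PhotocycleModel":
        names = list(cfg["states"])
        idx = {s: i for i, s in enumerate(names)}
        weights = np.zeros(len(names))
        for sname, w in cfg["open_state_weights"].items():
            weights[idx[sname]] = float(w)
        trans = [
            Transition(idx[t["from"]], idx[t["to"]], float(t["rate_ms"]),
                       bool(t.get("light", False)))
            for t in cfg["transitions"]
        ]
        return cls(
            name=str(cfg.get("name", "opsin")),
            state_names=names,
            dark_state_index=idx[cfg["dark_state"]],
            open_state_weights=weights,
            transitions=trans,
            g_max=float(cfg["g_max_mS_cm2"]),
            voltage_fn=dict(cfg["voltage_fn"]),
            light_dependence=dict(cfg["light_dependence"]),
            activation_wavelength_nm=float(
                cfg.get("activation_wavelength_nm", float("nan"))),
        )


@dataclass
class OpsinState:
    """Probability vector over photocycle states."""

    occupancy: np.ndarray

    def __post_init__(self):
        self.occupancy = np.asarray(self.occupancy, float)
        if self.occupancy.ndim != 1:
            raise ValueError("occupancy must be a vector")
        if abs(self.occupancy.sum() - 1.0) > 1e-9 or (self.occupancy < -1e-12).any():
            raise ValueError("occupancy is not a probability vector")


@dataclass
class OpsinPlacement:
    """Per-compartment expression scaling and irradiance for one opsin.

    ``scale[i]`` is dimensionless and multiplies g_max; the effective
    light-collecting area of compartment i is scale[i] * area[i] (um^2).
    """

    section_ids: np.ndarray
    scale: np.ndarray
    irradiance: np.ndarray  # mW/mm^2, set by the illumination stage

    def __post_init__(self):
        self.section_ids = np.asarray(self.section_ids, int)
        self.scale = np.asarray(self.scale, float)
        self.irradiance = np.asarray(self.irradiance, float)
        if (self.scale < 0).any():
            raise ValueError("scale factors must be >= 0")
        if (self.irradiance < 0).any():
            raise ValueError("irradiance must be >= 0")


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def available_presets() -> List[str]:
    pkg = importlib.resources.files("photogain") / "presets"
    return sorted(p.name[:-5] for p in pkg.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str, **overrides) -> PhotocycleModel:
    """Load a shipped opsin preset (e.g. ``chr2_6state``, ``nphr_6state``).

    Keyword overrides replace top-level preset keys (``g_max_mS_cm2``,
    ``voltage_fn``, ...) before construction.
    """
    res = importlib.resources.files("photogain") / "presets" / f"{name}.yaml"
    try:
        text = res.read_text()
    except FileNotFoundError:
        raise KeyError(
            f"unknown preset {name!r}; available: {available_presets()}"
        ) from None
    cfg = yaml.safe_load(text)
    cfg.update(overrides)
    return PhotocycleModel.from_dict(cfg)


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

def rate_matrix(model: PhotocycleModel, irradiance: float) -> np.ndarray:
    """Generator matrix Q (ms^-1): Q[i, j] is the i->j rate, rows sum to 0."""
    u = model.light_drive(irradiance)  # validates irradiance >= 0
    n = model.n_states
    Q = np.zeros((n, n))
    for tr in model.transitions:
        k = tr.rate * u if tr.light_gated else tr.rate
        Q[tr.source, tr.target] += k
    Q[np.diag_indices(n)] -= Q.sum(axis=1)
    return Q


_PROPAGATOR_CACHE: Dict[Tuple[bytes, float], np.ndarray] = {}


def propagator(generator: np.ndarray, dt: float) -> np.ndarray:
    """exp(Q*dt); cached so repeated stepping with a fixed Q is cheap."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    key = (generator.tobytes(), float(dt))
    P = _PROPAGATOR_CACHE.get(key)
    if P is None:
        P = scipy.linalg.expm(generator * dt)
        if len(_PROPAGATOR_CACHE) > 256:
            _PROPAGATOR_CACHE.clear()
        _PROPAGATOR_CACHE[key] = P
    return P


def step_occupancy(state: OpsinState, generator: np.ndarray,
                   dt: float) -> OpsinState:
    """Advance occupancy by dt with the exact matrix-exponential propagator.

    Exact for piecewise-constant light, hence unconditionally conservative
    and positivity preserving for any dt.
    """
    P = propagator(generator, dt)
    return OpsinState(state.occupancy @ P)


def steady_state_occupancy(model: PhotocycleModel,
                           irradiance: float) -> OpsinState:
    """Stationary distribution: the null space of Q^T, normalized to sum 1."""
    Q = rate_matrix(model, irradiance)
    ns = scipy.linalg.null_space(Q.T, rcond=1e-10)
    if ns.shape[1] != 1:
        raise ValueError(
            f"ambiguous steady state: null space has dimension {ns.shape[1]}")
    v = ns[:, 0]
    v = v / v.sum()
    v[np.abs(v) < 1e-14] = 0.0
    if (v < 0).any():
        raise ValueError("negative stationary occupancy (ill-conditioned Q)")
    return OpsinState(v)


def voltage_factor(model: PhotocycleModel, v_m: float) -> float:
    """Evaluate the voltage-dependence term f(V_m) in mV-equivalent units.

    Sign convention: positive f gives an outward (hyperpolarizing) membrane
    current, so a depolarizing opsin has f < 0 below its reversal.
    """
    fn = model.voltage_fn
    form = fn["form"]
    if form == "linear":
        return v_m - float(fn["e_rev_mV"])
    if form == "rectifier":
        u = float(fn.get("u_mV", 40.0))
        return u * (1.0 - np.exp(-(v_m - float(fn["e_rev_mV"])) / u))
    if form == "constant":
        return float(fn["drive_mV"])
    raise ValueError(f"unknown voltage_fn form {form!r}")


def conducting_fraction(model: PhotocycleModel, state: OpsinState) -> float:
    """psi: conductance-weighted open-state occupancy."""
    return float(model.open_state_weights @ state.occupancy)


def photocurrent(model: PhotocycleModel, state: OpsinState, v_m: float,
                 placement_scale: float) -> float:
    """Membrane photocurrent in nA (outward positive).

    ``placement_scale`` is the compartment's effective light-collecting
    area scale[i] * area[i] in um^2.
    """
    psi = conducting_fraction(model, state)
    return _CURRENT_UNIT * placement_scale * model.g_max * psi \
        * voltage_factor(model, v_m)


def decorate_inverse_area(arbor: Arbor, model: PhotocycleModel,
                          g_ref: float) -> OpsinPlacement:
    """Expression inversely proportional to compartment area.

    ``g_ref`` (um^2) is the constant effective area scale[i]*A[i]; under
    equal irradiance and equal voltage every compartment then produces an
    identical photocurrent, regardless of its size.  The soma is decorated
    along with every dendritic section.
    """
    if not g_ref > 0:
        raise ValueError("g_ref must be > 0")
    ids = [SOMA_ID] + [s.id for s in arbor.sections]
    areas = np.array([arbor.section(i).lateral_area for i in ids])
    if (areas <= 0).any():
        raise ValueError("zero-area compartment cannot be decorated")
    scale = g_ref / areas
    return OpsinPlacement(section_ids=np.array(ids), scale=scale,
                          irradiance=np.zeros(len(ids)))


def xnphr_condition(base_irr: float, x: float) -> Tuple[float, float]:
    """Irradiance pair (ChR2, NpHR) for NpHR:ChR2 illumination ratio x."""
    if base_irr < 0 or x < 0:
        raise ValueError("base_irr and x must be >= 0")
    return base_irr, x * base_irr
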