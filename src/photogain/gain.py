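"""Gain-modulation analysis: IF curves, the modulation index M, spike-train
statistics, and attenuation profiles.

The central quantity is the gain-modulation index

    M = (theta_ChR2 - theta_NpHR) / theta_balanced

where theta is the arctangent of the fitted slope of an IF curve plotting
the firing rate during photoactivation against the background rate of the
same run (measured in the epoch before light onset).  A slope change
(rotation of the IF curve) is gain modulation proper; a vertical offset is
a mere excitability shift, which the free-intercept fit deliberately
ignores.  M = 0 when ChR2- and NpHR-dominated illumination produce the
same rate transform; M > 0 when shifting the excitation:inhibition balance
of the photocurrents rotates the curve.

The study protocol driving these curves mimics transient presynaptic
input: compound synaptic volleys (one shared Poisson event train applied
to a handful of distal sites) whose shared weight is calibrated per
morphology so that the neuron relays volleys reliably - a loose form of
synaptic democracy.  Background drive rate is then swept, and illuminated
vs background rates are measured within single runs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .cable import (CableSystem, HHParams, IlluminationField, OpsinLight,
                    PassiveParams, Protocol, SynapseSpec, build_system, run,
                    steady_state_passive)
from .morphology import Arbor, MorphologySpec, SOMA_ID, generate_arbor, path_to_soma
from .opsins import (conducting_fraction, decorate_inverse_area,
                     load_preset, steady_state_occupancy, voltage_factor,
                     xnphr_condition)
from .synth import poisson_events, sample_synapse_sites

__all__ = [
    "IFCurve", "GainResult", "SpikeTrainStats", "StudyConfig",
    "fano_factor", "cv_isi", "spike_train_stats",
    "fit_if_curve", "modulation_index",
    "attenuation_profile", "AttenuationProfile",
    "make_study_system", "drive_sites", "calibrate_drive", "balanced_xnphr",
    "if_curve", "gain_for_condition", "sweep_modulation",
]


# ---------------------------------------------------------------------------
# Spike-train statistics
# ---------------------------------------------------------------------------

def fano_factor(spike_times: np.ndarray, window_ms: float,
                n_windows: int, t_start: float = 0.0) -> float:
    """Variance of per-window spike counts divided by their mean.

    The analysis epoch is ``n_windows`` consecutive windows of
    ``window_ms`` starting at ``t_start``.  Returns NaN (undefined) when
    the mean count is zero.
    """
    if window_ms <= 0 or n_windows < 2:
        raise ValueError("need window_ms > 0 and n_windows >= 2")
    st = np.asarray(spike_times, float)
    edges = t_start + window_ms * np.arange(n_windows + 1)
    counts, _ = np.histogram(st, bins=edges)
    mean = counts.mean()
    if mean == 0:
        return float("nan")
    return float(counts.var(ddof=1) / mean)


def cv_isi(spike_times: np.ndarray) -> float:
    """Coefficient of variation of interspike intervals (sd/mean, ddof=1).

    Returns NaN (undefined) with fewer than 3 spikes (< 2 ISIs).
    """
    st = np.asarray(spike_times, float)
    if st.size < 3:
        return float("nan")
    isi = np.diff(np.sort(st))
    return float(isi.std(ddof=1) / isi.mean())


@dataclass
class SpikeTrainStats:
    ff: float
    cv: float
    window_ms: float
    n_windows: int
    n_spikes: int

    @property
    def ff_defined(self) -> bool:
        return not math.isnan(self.ff)

    @property
    def cv_defined(self) -> bool:
        return not math.isnan(self.cv)


def spike_train_stats(spike_times: np.ndarray, window_ms: float = 100.0,
                      t_start: float = 0.0,
                      t_stop: Optional[float] = None) -> SpikeTrainStats:
    """FF and CV_ISI of one spike train over [t_start, t_stop)."""
    st = np.asarray(spike_times, float)
    if t_stop is None:
        t_stop = st.max() if st.size else t_start + window_ms
    n_windows = max(int((t_stop - t_start) // window_ms), 2)
    sel = st[(st >= t_start) & (st < t_start + n_windows * window_ms)]
    return SpikeTrainStats(
        ff=fano_factor(sel, window_ms, n_windows, t_start),
        cv=cv_isi(sel), window_ms=window_ms, n_windows=n_windows,
        n_spikes=int(sel.size))


# ---------------------------------------------------------------------------
# IF curves and the modulation index
# ---------------------------------------------------------------------------

@dataclass
class IFCurve:
    """Illuminated-vs-background rate curve for one illumination condition."""

    background: np.ndarray   # Hz
    illuminated: np.ndarray  # Hz
    slope: float
    intercept: float
    condition: dict = field(default_factory=dict)
    degenerate: bool = False

    @property
    def theta(self) -> float:
        """Angle of the fitted slope, radians."""
        return math.atan(self.slope)


def fit_if_curve(background: Sequence[float], illuminated: Sequence[float],
                 condition: Optional[dict] = None) -> IFCurve:
    """Least-squares line (free intercept) through the IF points."""
    bg = np.asarray(background, float)
    lit = np.asarray(illuminated, float)
    if bg.size != lit.size or bg.size < 2:
        raise ValueError("need >= 2 paired rate points")
    degenerate = bool(np.all(bg == 0) and np.all(lit == 0)) or np.ptp(bg) == 0
    if degenerate:
        slope, intercept = 0.0, float(lit.mean())
    else:
        slope, intercept = np.polyfit(bg, lit, 1)
    return IFCurve(background=bg, illuminated=lit, slope=float(slope),
                   intercept=float(intercept), condition=condition or {},
                   degenerate=degenerate)


@dataclass
class GainResult:
    M: float
    theta_chr2: float
    theta_nphr: float
    theta_balanced: float
    curves: Dict[str, IFCurve] = field(default_factory=dict)
    irradiance: float = float("nan")
    balanced_x: float = float("nan")
    spec: Optional[MorphologySpec] = None
    seed: Optional[int] = None

    @property
    def defined(self) -> bool:
        return not math.isnan(self.M)


def modulation_index(curve_chr2: IFCurve, curve_nphr: IFCurve,
                     curve_balanced: IFCurve) -> GainResult:
    """M = (theta_ChR2 - theta_NpHR) / theta_balanced, angles in radians.

    The balanced curve should sit near the identity; a warning is issued
    when its slope strays from 1 by more than 0.25.  A zero balanced angle
    makes M undefined (NaN), flagged rather than raised.
    """
    th_c = curve_chr2.theta
    th_n = curve_nphr.theta
    th_b = curve_balanced.theta
    if abs(curve_balanced.slope - 1.0) > 0.25:
        warnings.warn(
            f"balanced-condition slope {curve_balanced.slope:.3f} deviates "
            "from 1 by more than 0.25; M is normalized by an atypical angle",
            stacklevel=2)
    M = (th_c - th_n) / th_b if th_b != 0.0 else float("nan")
    return GainResult(M=M, theta_chr2=th_c, theta_nphr=th_n,
                      theta_balanced=th_b,
                      curves={"chr2": curve_chr2, "nphr": curve_nphr,
                              "balanced": curve_balanced})


# ---------------------------------------------------------------------------
# Attenuation profiles (passive steady state)
# ---------------------------------------------------------------------------

@dataclass
class AttenuationProfile:
    """Steady-state depolarization along paths of a passive arbor."""

    injection_site: int
    amplitude: float
    soma_path: pd.DataFrame          # columns: section_id, distance_um, dv_mV
    sister_path: Optional[pd.DataFrame]
    other_pole_path: Optional[pd.DataFrame]
    dv_by_section: Dict[int, float]


def _path_frame(system: CableSystem, ids: List[int],
                dv: Dict[int, float]) -> pd.DataFrame:
    arb = system.arbor
    rows = []
    for sid in ids:
        d = 0.0 if sid == SOMA_ID else arb.section(sid).mid_distance
        rows.append((sid, d, dv[sid]))
    return pd.DataFrame(rows, columns=["section_id", "distance_um", "dv_mV"])


def attenuation_profile(system: CableSystem, injection_site: int,
                        amplitude: float) -> AttenuationProfile:
    """Steady-state voltage deflection from distal injection, traced along
    the path to the soma plus a sister branch and another pole when present.

    Requires a passive system (no soma HH channels); the steady state is an
    exact sparse linear solve, and the deflection is measured relative to
    the unperturbed resting potential.
    """
    arb = system.arbor
    v = steady_state_passive(system, {injection_site: amplitude})
    v0 = steady_state_passive(system)
    dv = {}
    for sid in [SOMA_ID] + [s.id for s in arb.sections]:
        c = system.comp_of(sid)
        dv[sid] = float(v[c] - v0[c])

    main_path = path_to_soma(arb, injection_site)

    def descend_to_terminal(root_id: int) -> List[int]:
        out = [root_id]
        kids = arb.children(root_id)
        while kids:
            out.append(kids[0])
            kids = arb.children(kids[0])
        return out

    # sister: deepest branch point on the path with another child
    sister_ids = None
    inj_sec = arb.section(injection_site)
    for sid in main_path[1:]:  # walk rootward
        kids = [k for k in arb.children(sid) if k not in main_path]
        if kids:
            sister_ids = descend_to_terminal(kids[0]) + [sid]
            sister_ids = list(reversed(sister_ids))
            break
    other_ids = None
    for root in arb.children(SOMA_ID):
        if arb.section(root).pole_index != inj_sec.pole_index:
            other_ids = descend_to_terminal(root)
            break
    return AttenuationProfile(
        injection_site=injection_site, amplitude=amplitude,
        soma_path=_path_frame(system, main_path, dv),
        sister_path=_path_frame(system, sister_ids, dv) if sister_ids else None,
        other_pole_path=_path_frame(system, other_ids, dv) if other_ids else None,
        dv_by_section=dv)


# ---------------------------------------------------------------------------
# Study protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyConfig:
    """Protocol constants of the gain-modulation study.

    Drive: one shared Poisson volley train (minimum inter-volley gap
    ``min_gap_ms``) applied through ``n_sites`` excitatory synapses placed
    nearest-first beyond ``site_min_distance_um`` from the soma, balanced
    across poles.  The shared weight is calibrated so the neuron relays
    ``calib_fraction`` of volleys at the probe rate, then multiplied by
    ``weight_margin`` so that background relay is reliably suprathreshold.

    Timing: drive starts at ``t_drive_on``; the background epoch is scored
    from ``t_score`` to light onset ``t_light``; the illuminated epoch from
    ``t_light + transient_skip`` to ``t_end`` (onset transients excluded).

    The axial resistivity of the study systems is 150 Ohm*cm - a typical
    mammalian-dendrite value - which puts the electrotonic length constant
    of the 0.4 um sections near 0.6 mm, so arbors spanning 0.25-1.5 mm
    genuinely differ in how well distributed photocurrents reach the soma.
    """

    n_sites: int = 8
    site_min_distance_um: float = 100.0
    synapse_tau_ms: float = 2.0
    synapse_reversal_mV: float = 0.0
    min_gap_ms: float = 15.0
    g_ref_um2: float = 1.0           # effective light-collecting area/comp
    axial_resistivity: float = 150.0
    rates_hz: Tuple[float, ...] = (4.0, 8.0, 12.0, 16.0, 20.0)
    x_chr2_dominated: float = 0.25
    x_nphr_dominated: float = 4.0
    probe_rate_hz: float = 10.0
    calib_fraction: float = 0.85
    weight_margin: float = 1.3
    weight_bracket: Tuple[float, float] = (1e-4, 2.0)
    t_drive_on: float = 200.0
    t_score: float = 400.0
    t_light: float = 3400.0
    transient_skip: float = 400.0
    t_end: float = 6800.0
    n_seeds: int = 3
    chr2_preset: str = "chr2_6state"
    nphr_preset: str = "nphr_6state"


DEFAULT_STUDY = StudyConfig()


def make_study_system(spec_or_arbor: Union[MorphologySpec, Arbor],
                      config: StudyConfig = DEFAULT_STUDY
                      ) -> Tuple[Arbor, CableSystem]:
    """Arbor + simulatable system decorated with both opsins (study setup)."""
    arbor = (spec_or_arbor if isinstance(spec_or_arbor, Arbor)
             else generate_arbor(spec_or_arbor))
    chr2 = load_preset(config.chr2_preset)
    nphr = load_preset(config.nphr_preset)
    placements = [(chr2, decorate_inverse_area(arbor, chr2, config.g_ref_um2)),
                  (nphr, decorate_inverse_area(arbor, nphr, config.g_ref_um2))]
    system = build_system(
        arbor,
        passive=PassiveParams(axial_resistivity=config.axial_resistivity),
        hh_soma=HHParams(), opsin_placements=placements)
    return arbor, system


def drive_sites(arbor: Arbor, config: StudyConfig = DEFAULT_STUDY,
                seed: int = 0) -> List[int]:
    """Distal drive sites: nearest eligible sections, balanced over poles."""
    return sample_synapse_sites(
        arbor, config.n_sites, min_distance=config.site_min_distance_um,
        seed=seed, mode="equidistant", balance_poles=True)


def _volley_synapses(sites: Sequence[int], weight: float, times: np.ndarray,
                     config: StudyConfig) -> List[SynapseSpec]:
    return [SynapseSpec(sid, weight, tau=config.synapse_tau_ms,
                        reversal=config.synapse_reversal_mV,
                        event_times=times) for sid in sites]


def _volley_train(rate: float, t0: float, t1: float, seed: int,
                  config: StudyConfig) -> np.ndarray:
    return poisson_events(rate, t1 - t0, seed,
                          min_gap_ms=config.min_gap_ms) + t0


@dataclass
class DrivePlan:
    """Calibrated drive for one morphology: sites plus shared weight."""

    sites: List[int]
    weight: float
    feasible: bool
    saturation_rate_hz: float
    message: str = ""


def calibrate_drive(system: CableSystem, sites: Sequence[int],
                    config: StudyConfig = DEFAULT_STUDY,
                    calib_seed: int = 12345) -> DrivePlan:
    """Calibrate the shared volley weight (loose synaptic democracy).

    Measures the relay-saturation rate at the upper weight bracket, then
    bisects for the smallest weight that relays ``calib_fraction`` of that
    saturation at the probe rate, and applies the safety margin.  Flagged
    infeasible when the arbor cannot relay volleys at any weight - for
    deep, unbranched paths the transient simply does not survive to the
    soma.
    """
    t_end = 2600.0
    times = _volley_train(config.probe_rate_hz, config.t_drive_on, t_end,
                          calib_seed, config)

    def rate_of(w: float) -> float:
        syns = _volley_synapses(sites, w, times, config)
        res = run(system, Protocol(synapses=syns), t_end)
        return float(np.sum(res.spike_times >= config.t_score)
                     / ((t_end - config.t_score) / 1000.0))

    lo, hi = config.weight_bracket
    sat = rate_of(hi)
    if sat < 2.0:
        return DrivePlan(list(sites), float("nan"), False, sat,
                         "no transient relay at any weight in the bracket")
    target = config.calib_fraction * sat
    for _ in range(14):
        mid = math.sqrt(lo * hi)
        if rate_of(mid) >= target:
            hi = mid
        else:
            lo = mid
    return DrivePlan(list(sites), hi * config.weight_margin, True, sat,
                     "calibrated")


def balanced_xnphr(system: CableSystem, irradiance: float,
                   v_ref: float = -70.0) -> float:
    """NpHR:ChR2 irradiance ratio nulling the net steady photocurrent.

    Solved on the steady-state photocycle occupancies at a reference
    membrane potential; with both opsins decorated uniformly the same ratio
    balances any coverage mask, so one value serves a whole sweep.
    """
    if irradiance <= 0:
        return 1.0
    if len(system.opsins) != 2:
        raise ValueError("balanced_xnphr expects a ChR2 + NpHR system")
    (chr2, gp_c), (nphr, gp_n) = system.opsins

    def net(x: float) -> float:
        tot = 0.0
        for model, gpref, phi in ((chr2, gp_c, irradiance),
                                  (nphr, gp_n, irradiance * x)):
            ss = steady_state_occupancy(model, phi)
            tot += (gpref.sum() * conducting_fraction(model, ss)
                    * voltage_factor(model, v_ref))
        return tot

    lo, hi = 1e-3, 100.0
    if net(lo) > 0:   # NpHR dominant even at negligible ratio
        return lo
    if net(hi) < 0:   # ChR2 cannot be nulled within the bracket
        return hi
    for _ in range(60):
        mid = math.sqrt(lo * hi)
        if net(mid) < 0:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def _illumination(system: CableSystem, irradiance: float, x: float,
                  coverage: Optional[Sequence[int]],
                  config: StudyConfig) -> Optional[IlluminationField]:
    if irradiance <= 0:
        return None
    irr_c, irr_n = xnphr_condition(irradiance, x)
    names = system.opsin_names
    return IlluminationField({
        names[0]: OpsinLight(irr_c, config.t_light, config.t_end,
                             coverage=coverage),
        names[1]: OpsinLight(irr_n, config.t_light, config.t_end,
                             coverage=coverage)})


def _rate_pair(system: CableSystem, plan: DrivePlan, rate: float,
               illumination: Optional[IlluminationField], seed: int,
               config: StudyConfig) -> Tuple[float, float]:
    times = _volley_train(rate, config.t_drive_on, config.t_end, seed, config)
    syns = _volley_synapses(plan.sites, plan.weight, times, config)
    res = run(system, Protocol(synapses=syns, illumination=illumination),
              config.t_end)
    st = res.spike_times
    bg_T = (config.t_light - config.t_score) / 1000.0
    lit_T = (config.t_end - config.t_light - config.transient_skip) / 1000.0
    bg = float(np.sum((st >= config.t_score) & (st < config.t_light)) / bg_T)
    lit = float(np.sum(st >= config.t_light + config.transient_skip) / lit_T)
    return bg, lit


def if_curve(system: CableSystem, plan: DrivePlan, irradiance: float,
             x: float, seed: int, coverage: Optional[Sequence[int]] = None,
             config: StudyConfig = DEFAULT_STUDY) -> IFCurve:
    """One IF curve: sweep drive rates, one run per rate and seed replicate.

    Background and illuminated rates come from the pre-light and lit epochs
    of the same run, so the same frozen drive realization underlies both
    axes of every point.  ``config.n_seeds`` independent drive realizations
    per rate are pooled before the line fit.
    """
    bg_all: List[float] = []
    lit_all: List[float] = []
    ill = _illumination(system, irradiance, x, coverage, config)
    for k in range(config.n_seeds):
        for i, rate in enumerate(config.rates_hz):
            bg, lit = _rate_pair(system, plan, rate, ill,
                                 seed + 31 * i + 104729 * k, config)
            bg_all.append(bg)
            lit_all.append(lit)
    return fit_if_curve(bg_all, lit_all,
                        condition={"irradiance": irradiance, "xNpHR": x,
                                   "seed": seed})


def gain_for_condition(system: CableSystem, plan: DrivePlan,
                       irradiance: float, seed: int,
                       coverage: Optional[Sequence[int]] = None,
                       balanced_x: Optional[float] = None,
                       config: StudyConfig = DEFAULT_STUDY) -> GainResult:
    """Gain index for one (morphology, irradiance, coverage) condition."""
    xb = balanced_x if balanced_x is not None \
        else balanced_xnphr(system, irradiance)
    conditions = {"chr2": config.x_chr2_dominated, "balanced": xb,
                  "nphr": config.x_nphr_dominated}
    curves = {lab: if_curve(system, plan, irradiance, x, seed, coverage,
                            config)
              for lab, x in conditions.items()}
    result = modulation_index(curves["chr2"], curves["nphr"],
                              curves["balanced"])
    result.irradiance = irradiance
    result.balanced_x = xb
    result.seed = seed
    return result


def sweep_modulation(spec_grid: Sequence[MorphologySpec],
                     irr_grid: Sequence[float],
                     seed: int = 0,
                     xnphr_set: Optional[Tuple[float, float]] = None,
                     config: StudyConfig = DEFAULT_STUDY) -> pd.DataFrame:
    """M over a morphology x irradiance grid, as a long-format table.

    Cells whose drive cannot be calibrated (no transient relay) are
    recorded with NaN M and ``feasible = False`` rather than dropped.
    Columns: n_p, n_b, n_l, irr, xNpHR_balanced, slope_* and theta_* per
    condition, M, feasible, seed.
    """
    if xnphr_set is not None:
        config = replace(config, x_chr2_dominated=xnphr_set[0],
                         x_nphr_dominated=xnphr_set[1])
    rows = []
    for spec in spec_grid:
        arbor, system = make_study_system(spec, config)
        sites = drive_sites(arbor, config, seed=seed)
        plan = calibrate_drive(system, sites, config)
        for irr in irr_grid:
            row = {"n_p": spec.n_p, "n_b": spec.n_b, "n_l": spec.n_levels,
                   "irr": irr, "seed": seed, "feasible": plan.feasible}
            if not plan.feasible:
                row.update({"M": float("nan"), "xNpHR_balanced": float("nan")})
            else:
                g = gain_for_condition(system, plan, irr, seed, config=config)
                row.update({
                    "M": g.M, "xNpHR_balanced": g.balanced_x,
                    "slope_chr2": g.curves["chr2"].slope,
                    "slope_balanced": g.curves["balanced"].slope,
                    "slope_nphr": g.curves["nphr"].slope,
                    "theta_chr2": g.theta_chr2,
                    "theta_balanced": g.theta_balanced,
                    "theta_nphr": g.theta_nphr,
                })
            rows.append(row)
    return pd.DataFrame(rows)
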