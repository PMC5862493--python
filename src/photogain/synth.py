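"""Synthetic inputs: Poisson presynaptic trains, frozen-noise realizations,
synapse-site sampling, and SWC fixture morphologies.

Everything the simulation pipeline consumes can be generated here with an
explicit seed, so the package is fully testable offline.  The two fixture
morphologies are *synthetic stand-ins* - parametric arbors shaped and
sized like a layer-5 pyramidal cell (bipolar, tapered trunk, dendritic
area near 60,000 um^2) and a spiny stellate cell (multipolar, sparse
branching, near 30,000 um^2).  They are not reconstructions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, TextIO, Union

import numpy as np

from .morphology import Arbor, ROOT_MARKER, SOMA_ID, Section, write_swc

__all__ = [
    "DriveSpec", "FrozenDrive", "poisson_events", "poisson_trains",
    "frozen_noise", "sample_synapse_sites", "fixture_morphologies",
]


# ---------------------------------------------------------------------------
# Poisson trains
# ---------------------------------------------------------------------------

def poisson_events(rate_hz: float, duration_ms: float, seed: int,
                   min_gap_ms: float = 0.0) -> np.ndarray:
    """One event-time train in [0, duration) ms.

    ``min_gap_ms = 0`` gives a homogeneous Poisson process; a positive gap
    produces a Poisson process with dead time (each exponential inter-event
    interval is floored at the gap), used for compound-volley drive.
    """
    if rate_hz < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    if rate_hz == 0 or duration_ms <= 0:
        return np.empty(0)
    if min_gap_ms <= 0:
        n = rng.poisson(rate_hz * duration_ms / 1000.0)
        return np.sort(rng.uniform(0.0, duration_ms, n))
    out = []
    t = 0.0
    mean_gap = 1000.0 / rate_hz
    while True:
        t += max(rng.exponential(mean_gap), min_gap_ms)
        if t >= duration_ms:
            break
        out.append(t)
    return np.asarray(out)


def poisson_trains(n_sites: int, rate_hz: float, duration_ms: float,
                   seed: int) -> List[np.ndarray]:
    """Independent homogeneous Poisson trains, one per site."""
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    seq = np.random.SeedSequence(seed)
    return [poisson_events(rate_hz, duration_ms, child)
            for child in seq.generate_state(n_sites)]


@dataclass(frozen=True)
class DriveSpec:
    """Presynaptic drive specification."""

    n_excitatory_sites: int
    rate_hz: float
    duration_ms: float
    seed: int
    n_inhibitory_sites: int = 0
    min_distance_to_soma_um: float = 100.0
    frozen: bool = False

    def __post_init__(self):
        if self.n_excitatory_sites < 0 or self.n_inhibitory_sites < 0:
            raise ValueError("site counts must be >= 0")
        if self.duration_ms <= 0:
            raise ValueError("duration must be > 0")


@dataclass
class FrozenDrive:
    """A fixed realization of a DriveSpec, reusable across conditions."""

    spec: DriveSpec
    trains: List[np.ndarray]

    @property
    def n_sites(self) -> int:
        return len(self.trains)

    def to_csv(self, path_or_stream: Union[str, Path, TextIO]) -> None:
        if isinstance(path_or_stream, (str, Path)):
            with open(path_or_stream, "w") as fh:
                self.to_csv(fh)
            return
        fh = path_or_stream
        fh.write("site_id,t_ms\n")
        for i, train in enumerate(self.trains):
            for t in train:
                fh.write(f"{i},{float(t)!r}\n")

    @classmethod
    def from_csv(cls, path_or_stream: Union[str, Path, TextIO],
                 spec: Optional[DriveSpec] = None) -> "FrozenDrive":
        if isinstance(path_or_stream, (str, Path)):
            with open(path_or_stream) as fh:
                return cls.from_csv(fh, spec)
        fh = path_or_stream
        header = fh.readline()
        if header.strip() != "site_id,t_ms":
            raise ValueError("expected 'site_id,t_ms' header")
        by_site: Dict[int, List[float]] = {}
        n_max = -1
        for line in fh:
            if not line.strip():
                continue
            sid_s, t_s = line.split(",")
            sid = int(sid_s)
            by_site.setdefault(sid, []).append(float(t_s))
            n_max = max(n_max, sid)
        trains = [np.asarray(by_site.get(i, []), float)
                  for i in range(n_max + 1)]
        if spec is None:
            spec = DriveSpec(n_excitatory_sites=len(trains), rate_hz=float("nan"),
                             duration_ms=float("inf"), seed=-1, frozen=True)
        return cls(spec=spec, trains=trains)


def frozen_noise(spec: DriveSpec) -> FrozenDrive:
    """Materialize one reusable noise realization from a frozen DriveSpec."""
    if not spec.frozen:
        raise ValueError("frozen_noise requires a DriveSpec with frozen=True")
    n = spec.n_excitatory_sites + spec.n_inhibitory_sites
    return FrozenDrive(spec=spec,
                       trains=poisson_trains(n, spec.rate_hz,
                                             spec.duration_ms, spec.seed))


# ---------------------------------------------------------------------------
# Synapse-site sampling
# ---------------------------------------------------------------------------

def sample_synapse_sites(arbor: Arbor, n_sites: int,
                         min_distance: float = 0.0,
                         subdomain_constraints: Optional[Dict[int, int]] = None,
                         seed: int = 0,
                         mode: str = "uniform",
                         balance_poles: bool = False,
                         distance_bin_um: float = 10.0) -> List[int]:
    """Sample synapse locations (section ids) on an arbor.

    Eligible sections have midpoint path distance >= ``min_distance`` um
    from the soma.  ``subdomain_constraints`` maps pole index -> quota
    (e.g. 80 apical + 80 basal); sampling is without replacement within
    each quota.  ``mode='uniform'`` samples uniformly among eligible
    sections; ``mode='equidistant'`` prefers sections whose distance is
    closest to ``min_distance``, binning distances at ``distance_bin_um``
    and sampling uniformly inside bins (the rule used for stellate-like
    drive at a target distance).  ``balance_poles`` deals sites round-robin
    across poles.  Selection depends only on the seed and the eligible set,
    not on section ordering.
    """
    if n_sites < 0:
        raise ValueError("n_sites must be >= 0")
    rng = np.random.default_rng(seed)
    eligible = sorted((s for s in arbor.sections
                       if s.mid_distance >= min_distance),
                      key=lambda s: s.id)
    by_pole: Dict[int, List[Section]] = {}
    for s in eligible:
        by_pole.setdefault(s.pole_index, []).append(s)

    def sort_key(sec: Section):
        if mode == "equidistant":
            b = math.floor((sec.mid_distance - min_distance)
                           / distance_bin_um)
            return (b, rng.random())
        if mode == "uniform":
            return rng.random()
        raise ValueError("mode must be 'uniform' or 'equidistant'")

    if subdomain_constraints is not None:
        chosen: List[int] = []
        problems = []
        for pole, quota in subdomain_constraints.items():
            avail = by_pole.get(pole, [])
            if quota > len(avail):
                problems.append((pole, quota, len(avail)))
        if problems:
            detail = "; ".join(
                f"pole {p}: requested {q}, eligible {a}"
                for p, q, a in problems)
            raise ValueError(
                f"infeasible synapse-site quota ({detail}) at "
                f"min_distance {min_distance} um")
        for pole, quota in subdomain_constraints.items():
            ordered = sorted(by_pole[pole], key=sort_key)
            chosen.extend(s.id for s in ordered[:quota])
        return chosen

    if n_sites > len(eligible):
        raise ValueError(
            f"requested {n_sites} sites but only {len(eligible)} sections "
            f"are >= {min_distance} um from the soma")
    if balance_poles and by_pole:
        queues = {p: sorted(v, key=sort_key) for p, v in by_pole.items()}
        poles = sorted(queues)
        chosen = []
        i = 0
        while len(chosen) < n_sites:
            p = poles[i % len(poles)]
            if queues[p]:
                chosen.append(queues[p].pop(0).id)
            i += 1
        return chosen
    ordered = sorted(eligible, key=sort_key)
    return [s.id for s in ordered[:n_sites]]


# ---------------------------------------------------------------------------
# Fixture morphologies (synthetic stand-ins)
# ---------------------------------------------------------------------------

class _Builder:
    def __init__(self, soma_diameter: float):
        self.soma = Section(id=SOMA_ID, parent_id=ROOT_MARKER,
                            length=soma_diameter, diameter=soma_diameter,
                            depth_level=-1, pole_index=-1,
                            path_distance_to_soma=0.0)
        self.sections: List[Section] = []
        self._next = 1

    def add(self, parent: Section, length: float, diameter: float) -> Section:
        if parent.id == SOMA_ID:
            depth, pole, dist = 0, self._pole_count(), 0.0
        else:
            depth = parent.depth_level + 1
            pole = parent.pole_index
            dist = parent.path_distance_to_soma + parent.length
        sec = Section(id=self._next, parent_id=parent.id, length=length,
                      diameter=diameter, depth_level=depth, pole_index=pole,
                      path_distance_to_soma=dist)
        self._next += 1
        self.sections.append(sec)
        return sec

    def _pole_count(self) -> int:
        return sum(1 for s in self.sections if s.parent_id == SOMA_ID)

    def chain(self, parent: Section, n: int, length: float,
              diameter: float) -> Section:
        for _ in range(n):
            parent = self.add(parent, length, diameter)
        return parent

    def scale_to_area(self, target_um2: float) -> None:
        area = sum(s.lateral_area for s in self.sections)
        f = target_um2 / area
        self.sections = [
            Section(id=s.id, parent_id=s.parent_id, length=s.length,
                    diameter=s.diameter * f, depth_level=s.depth_level,
                    pole_index=s.pole_index,
                    path_distance_to_soma=s.path_distance_to_soma)
            for s in self.sections]

    def build(self, tag: str) -> Arbor:
        return Arbor(soma=self.soma, sections=self.sections, spec=tag)


def _pyramidal_like() -> Arbor:
    """Bipolar fixture: tapered apical trunk with obliques and a tuft, plus
    a dense basal tree; dendritic area scaled to 60,000 um^2 and a soma of
    1,131 um^2 (equivalent cylinder)."""
    b = _Builder(soma_diameter=math.sqrt(1131.0 / math.pi))
    # apical pole: trunk of 8 x 100 um, tapering
    trunk = b.soma
    trunk_secs = []
    for i in range(8):
        d = 6.0 - 0.45 * i
        trunk = b.add(trunk, 100.0, d)
        trunk_secs.append(trunk)
    # obliques from trunk sections 2..7: 3-section chains
    for t in trunk_secs[2:]:
        b.chain(t, 3, 80.0, 1.2)
    # tuft: binary tree, 5 stages
    frontier = [trunk]
    for _ in range(5):
        frontier = [b.add(p, 80.0, 1.5) for p in frontier for _ in range(2)]
    # basal pole: short trunk, 8 subtrees of 4 binary stages
    basal = b.add(b.soma, 40.0, 4.0)
    for _ in range(8):
        frontier = [b.add(basal, 60.0, 1.8)]
        for _ in range(3):
            frontier = [b.add(p, 60.0, 1.4) for p in frontier for _ in range(2)]
    b.scale_to_area(60_000.0)
    return b.build("synthetic_pyramidal")


def _stellate_like() -> Arbor:
    """Multipolar fixture: 8 primaries, one bifurcation stage each, children
    extended as 2-section chains; dendritic area scaled to 30,000 um^2."""
    b = _Builder(soma_diameter=15.0)
    for _ in range(8):
        prim = b.add(b.soma, 80.0, 3.0)
        for _ in range(3):
            b.chain(prim, 2, 60.0, 2.0)
    b.scale_to_area(30_000.0)
    return b.build("synthetic_stellate")


def fixture_morphologies(out_dir: Optional[Union[str, Path]] = None
                         ) -> Dict[str, Arbor]:
    """Deterministic synthetic stand-in morphologies.

    Returns ``{"synthetic_pyramidal": ..., "synthetic_stellate": ...}``;
    when ``out_dir`` is given, also writes ``<name>.swc`` files there.
    """
    fixtures = {"synthetic_pyramidal": _pyramidal_like(),
                "synthetic_stellate": _stellate_like()}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, arb in fixtures.items():
            write_swc(arb, str(out / f"{name}.swc"))
    return fixtures
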