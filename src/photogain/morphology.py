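"""Parametric dendritic arbors and SWC morphology I/O.

Abstract arbors are described by three integers: the number of primary
branches leaving the soma (``n_p``, the polarity), the number of sister
branches spawned at every bifurcation (``n_b``), and the number of
branching stages (``n_levels``, counting the creation of the primaries as
the first stage).  All sections are untapered cylinders of identical
length and diameter, so rearranging (n_p, n_b, n_levels) at a fixed total
section count changes the arbor's topology while conserving its membrane
area.  The soma is a single equivalent cylinder.

SWC read/write supports the plain 7-column dialect
(id, type, x, y, z, radius, parent; ``#`` comments; parent ``-1`` for the
root).  Multi-point somas are collapsed to one cylinder of equivalent
lateral area, since the simulator treats the soma as a single compartment.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, TextIO, Tuple, Union

import numpy as np

__all__ = [
    "MorphologySpec",
    "Section",
    "Arbor",
    "count_branches",
    "generate_arbor",
    "total_membrane_area",
    "path_to_soma",
    "read_swc",
    "write_swc",
    "SwcFormatError",
]

SOMA_ID = 0
ROOT_MARKER = -1

#: SWC structure-type codes
SWC_SOMA = 1
SWC_DENDRITE = 3


class SwcFormatError(ValueError):
    """Raised for malformed SWC input; carries the offending line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class MorphologySpec:
    """Parameter triplet plus per-section geometry of an abstract arbor.

    Defaults follow the abstract-model geometry used throughout the
    package: 50 um x 0.4 um dendritic sections and a 10 um x 10 um soma.
    """

    n_p: int
    n_b: int
    n_levels: int
    section_length: float = 50.0
    section_diameter: float = 0.4
    soma_length: float = 10.0
    soma_diameter: float = 10.0

    def __post_init__(self):
        for name in ("n_p", "n_b", "n_levels"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        for name in ("section_length", "section_diameter", "soma_length",
                     "soma_diameter"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v!r}")

    @property
    def n_sections(self) -> int:
        return count_branches(self.n_p, self.n_b, self.n_levels)


@dataclass
class Section:
    """One cylindrical dendritic section.

    ``path_distance_to_soma`` is the distance along the tree from the soma
    surface to the *proximal* end of the section; primaries start at 0.
    """

    id: int
    parent_id: int  # SOMA_ID for primaries; ROOT_MARKER only for the soma itself
    length: float
    diameter: float
    depth_level: int  # 0 = attached to the soma
    pole_index: int
    path_distance_to_soma: float

    @property
    def lateral_area(self) -> float:
        """Lateral cylinder area pi*d*L in um^2 (end caps excluded)."""
        return math.pi * self.diameter * self.length

    @property
    def mid_distance(self) -> float:
        """Path distance from soma to the section midpoint (um)."""
        return self.path_distance_to_soma + 0.5 * self.length


@dataclass
class Arbor:
    """A soma-rooted tree of cylindrical sections."""

    soma: Section
    sections: List[Section]
    spec: Union[MorphologySpec, str, None] = None
    #: optional 3D sample coordinates per id (for SWC round trips)
    coords: Dict[int, Tuple[float, float, float]] = field(default_factory=dict)

    def __post_init__(self):
        self._index: Dict[int, Section] = {s.id: s for s in self.sections}
        if self.soma.id in self._index:
            raise ValueError("soma id collides with a section id")
        self._children: Dict[int, List[int]] = {self.soma.id: []}
        for s in self.sections:
            self._children.setdefault(s.id, [])
        for s in self.sections:
            if s.parent_id != self.soma.id and s.parent_id not in self._index:
                raise ValueError(f"section {s.id} references missing parent "
                                 f"{s.parent_id}")
            self._children[s.parent_id].append(s.id)

    def __len__(self) -> int:
        return len(self.sections)

    def section(self, section_id: int) -> Section:
        if section_id == self.soma.id:
            return self.soma
        try:
            return self._index[section_id]
        except KeyError:
            raise KeyError(f"no section with id {section_id}") from None

    def children(self, section_id: int) -> List[int]:
        return list(self._children.get(section_id, []))

    @property
    def n_poles(self) -> int:
        return len(self._children[self.soma.id])

    def pole_sections(self, pole_index: int) -> List[Section]:
        out = [s for s in self.sections if s.pole_index == pole_index]
        if not out:
            raise KeyError(f"no pole with index {pole_index}")
        return out

    def terminals(self) -> List[Section]:
        return [s for s in self.sections if not self._children[s.id]]

    def topological_hash(self) -> int:
        """Relabelling-invariant hash of the tree shape (with geometry)."""
        def h(sid: int) -> int:
            sec = self.section(sid)
            kids = tuple(sorted(h(c) for c in self._children[sid]))
            return hash((round(sec.length, 4), round(sec.diameter, 4), kids))
        kids = tuple(sorted(h(c) for c in self._children[self.soma.id]))
        return hash(kids)

    def pole_hash(self, pole_index: int) -> int:
        """Relabelling-invariant hash of one pole subtree."""
        roots = [c for c in self._children[self.soma.id]
                 if self.section(c).pole_index == pole_index]
        if not roots:
            raise KeyError(f"no pole with index {pole_index}")

        def h(sid: int) -> int:
            sec = self.section(sid)
            kids = tuple(sorted(h(c) for c in self._children[sid]))
            return hash((round(sec.length, 6), round(sec.diameter, 6), kids))

        return hash(tuple(sorted(h(r) for r in roots)))


def count_branches(n_p: int, n_b: int, n_levels: int) -> int:
    """Total number of dendritic sections of an abstract arbor.

    N_total = n_p * sum_{k=0}^{n_levels-1} n_b**k  -- i.e. each of the n_p
    primaries heads a tree in which every terminal spawns n_b children at
    each of the remaining n_levels-1 stages.
    """
    for name, v in (("n_p", n_p), ("n_b", n_b), ("n_levels", n_levels)):
        if not isinstance(v, (int, np.integer)) or v < 1:
            raise ValueError(f"{name} must be a positive integer, got {v!r}")
    return int(n_p) * sum(int(n_b) ** k for k in range(int(n_levels)))


def generate_arbor(spec: MorphologySpec) -> Arbor:
    """Generate the symmetric abstract arbor described by ``spec``.

    The n_p pole subtrees are isomorphic by construction; sections are
    emitted in breadth-first order so parents always precede children.
    """
    soma = Section(id=SOMA_ID, parent_id=ROOT_MARKER, length=spec.soma_length,
                   diameter=spec.soma_diameter, depth_level=-1, pole_index=-1,
                   path_distance_to_soma=0.0)
    sections: List[Section] = []
    next_id = 1
    frontier: List[Section] = []
    for p in range(spec.n_p):
        s = Section(id=next_id, parent_id=SOMA_ID, length=spec.section_length,
                    diameter=spec.section_diameter, depth_level=0,
                    pole_index=p, path_distance_to_soma=0.0)
        next_id += 1
        sections.append(s)
        frontier.append(s)
    for _level in range(1, spec.n_levels):
        new_frontier: List[Section] = []
        for parent in frontier:
            for _ in range(spec.n_b):
                s = Section(
                    id=next_id, parent_id=parent.id,
                    length=spec.section_length,
                    diameter=spec.section_diameter,
                    depth_level=parent.depth_level + 1,
                    pole_index=parent.pole_index,
                    path_distance_to_soma=parent.path_distance_to_soma
                    + parent.length,
                )
                next_id += 1
                sections.append(s)
                new_frontier.append(s)
        frontier = new_frontier
    arbor = Arbor(soma=soma, sections=sections, spec=spec)
    assert len(arbor) == spec.n_sections
    return arbor


def total_membrane_area(arbor: Arbor) -> Tuple[float, float]:
    """(soma_area, dendrite_area) in um^2; lateral areas only."""
    soma_area = arbor.soma.lateral_area
    dend_area = float(sum(s.lateral_area for s in arbor.sections))
    return soma_area, dend_area


def path_to_soma(arbor: Arbor, section_id: int) -> List[int]:
    """Ids from the given section to the soma, inclusive of both ends."""
    sec = arbor.section(section_id)  # raises KeyError for unknown ids
    if section_id == arbor.soma.id:
        return [arbor.soma.id]
    path = [section_id]
    while sec.parent_id != ROOT_MARKER:
        path.append(sec.parent_id)
        if sec.parent_id == arbor.soma.id:
            break
        sec = arbor.section(sec.parent_id)
    return path


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def _layout_positions(arbor: Arbor) -> Dict[int, Tuple[float, float, float]]:
    """Cosmetic 2D fan layout for abstract arbors (z = 0).

    Poles leave the soma at equal angles; at each bifurcation children fan
    symmetrically inside a shrinking angular aperture.  Positions do not
    affect simulation.
    """
    pos: Dict[int, Tuple[float, float, float]] = {SOMA_ID: (0.0, 0.0, 0.0)}
    n_poles = max(arbor.n_poles, 1)

    def place(sid: int, origin, angle: float, aperture: float):
        sec = arbor.section(sid)
        x = origin[0] + sec.length * math.cos(angle)
        y = origin[1] + sec.length * math.sin(angle)
        pos[sid] = (x, y, 0.0)
        kids = arbor.children(sid)
        if kids:
            span = aperture
            for i, kid in enumerate(kids):
                if len(kids) == 1:
                    a = angle
                else:
                    a = angle - span / 2 + span * i / (len(kids) - 1)
                place(kid, (x, y), a, aperture * 0.6)

    roots = arbor.children(SOMA_ID)
    for i, r in enumerate(roots):
        angle = 2 * math.pi * i / n_poles
        place(r, (0.0, 0.0), angle, math.pi / n_poles)
    return pos


def write_swc(arbor: Arbor, stream: Union[str, TextIO]) -> None:
    """Write an arbor as 7-column SWC.

    The soma is written as a single root sample whose radius encodes the
    equivalent cylinder (d = L = 2r convention).  Each section becomes one
    sample at its distal end.
    """
    if isinstance(stream, str):
        with open(stream, "w") as fh:
            write_swc(arbor, fh)
        return
    coords = arbor.coords or _layout_positions(arbor)
    # SWC ids must be >= 1; shift internal ids by +1
    stream.write("# generated by photogain\n")
    stream.write("# id type x y z radius parent\n")
    sx, sy, sz = coords.get(SOMA_ID, (0.0, 0.0, 0.0))
    soma_r = arbor.soma.diameter / 2.0
    stream.write(f"1 {SWC_SOMA} {sx:.9g} {sy:.9g} {sz:.9g} {soma_r:.9g} -1\n")
    for s in arbor.sections:
        x, y, z = coords[s.id]
        stream.write(
            f"{s.id + 1} {SWC_DENDRITE} {x:.9g} {y:.9g} {z:.9g} "
            f"{s.diameter / 2.0:.9g} {s.parent_id + 1}\n")


def read_swc(stream: Union[str, TextIO]) -> Arbor:
    """Parse SWC into an :class:`Arbor`.

    All leading contiguous soma-type samples are collapsed into one
    equivalent cylinder (equal lateral area, d = L).  Every non-soma sample
    becomes one section whose length is the Euclidean distance to its
    parent sample and whose diameter is twice its own radius.
    """
    if isinstance(stream, str):
        with open(stream) as fh:
            return read_swc(fh)
    samples: Dict[int, Tuple[int, float, float, float, float, int, int]] = {}
    order: List[int] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SwcFormatError(f"expected 7 columns, got {len(parts)}", lineno)
        try:
            sid = int(parts[0])
            stype = int(parts[1])
            x, y, z, r = (float(p) for p in parts[2:6])
            parent = int(parts[6])
        except ValueError as exc:
            raise SwcFormatError(f"unparseable field ({exc})", lineno) from None
        if sid in samples:
            raise SwcFormatError(f"duplicate sample id {sid}", lineno)
        if r <= 0:
            raise SwcFormatError(f"non-positive radius {r}", lineno)
        if parent != -1 and parent not in samples:
            raise SwcFormatError(
                f"parent {parent} of sample {sid} not yet defined "
                "(missing or out of order)", lineno)
        samples[sid] = (stype, x, y, z, r, parent, lineno)
        order.append(sid)
    if not order:
        raise SwcFormatError("empty SWC: no samples")

    # soma = all samples of type 1
    soma_ids = [sid for sid in order if samples[sid][0] == SWC_SOMA]
    if not soma_ids:
        raise SwcFormatError("no soma sample (type 1) found")
    root_candidates = [sid for sid in order if samples[sid][5] == -1]
    if len(root_candidates) != 1:
        raise SwcFormatError(
            f"expected exactly one root sample, found {len(root_candidates)}")

    # equivalent soma cylinder: sum lateral areas of soma frusta
    if len(soma_ids) == 1:
        r = samples[soma_ids[0]][4]
        soma_len = soma_diam = 2.0 * r
    else:
        area = 0.0
        for sid in soma_ids:
            stype, x, y, z, r, parent, _ = samples[sid]
            if parent in soma_ids:
                px, py, pz, pr = samples[parent][1:5]
                h = math.dist((x, y, z), (px, py, pz))
                area += math.pi * (r + pr) * h
        if area <= 0.0:  # coincident points: fall back to the root sphere
            r = samples[root_candidates[0]][4]
            soma_len = soma_diam = 2.0 * r
        else:
            soma_len = soma_diam = math.sqrt(area / math.pi)

    soma = Section(id=SOMA_ID, parent_id=ROOT_MARKER, length=soma_len,
                   diameter=soma_diam, depth_level=-1, pole_index=-1,
                   path_distance_to_soma=0.0)

    # map SWC sample ids -> internal section ids (soma samples -> SOMA_ID)
    id_map: Dict[int, int] = {sid: SOMA_ID for sid in soma_ids}
    coords: Dict[int, Tuple[float, float, float]] = {}
    root_xyz = samples[root_candidates[0]][1:4]
    coords[SOMA_ID] = tuple(root_xyz)

    sections: List[Section] = []
    next_id = 1
    pole_counter = 0
    for sid in order:
        stype, x, y, z, r, parent, lineno = samples[sid]
        if stype == SWC_SOMA:
            if parent != -1 and parent not in soma_ids:
                raise SwcFormatError(
                    f"soma sample {sid} attached to non-soma parent", lineno)
            continue
        if parent == -1:
            raise SwcFormatError(
                f"non-soma sample {sid} cannot be the root", lineno)
        pid = id_map[parent]
        if pid == SOMA_ID:
            parent_xyz = root_xyz
            depth = 0
            pole = pole_counter
            pole_counter += 1
            pdist = 0.0
        else:
            psec = sections[pid - 1]
            parent_xyz = coords[pid]
            depth = psec.depth_level + 1
            pole = psec.pole_index
            pdist = psec.path_distance_to_soma + psec.length
        length = math.dist((x, y, z), parent_xyz)
        if length <= 0:
            length = 1e-6  # degenerate zero-length segment
        sec = Section(id=next_id, parent_id=pid, length=length, diameter=2 * r,
                      depth_level=depth, pole_index=pole,
                      path_distance_to_soma=pdist)
        id_map[sid] = next_id
        coords[next_id] = (x, y, z)
        sections.append(sec)
        next_id += 1
    return Arbor(soma=soma, sections=sections, spec="swc", coords=coords)
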