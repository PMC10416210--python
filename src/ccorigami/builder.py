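"""Idealized coiled-coil origami builder.

A triangular origami is one polypeptide chain that traverses the three
edges of a triangle twice, so that each edge carries a parallel CC dimer
whose two helices are visited three segments apart.  The builder realizes
this as a supercoil around each edge midline: the dimer pair plane rotates
by 180° along every edge, so each helix axis crosses the triangle plane
and the segments alternate between packing on the inner and the outer
side of the triangle.  Traversed twice with a uniform sense of rotation,
the chain closes into a (2,3)-torus curve — a trefoil knot.  Holding the
pair plane inside the triangle plane instead gives the unknotted planar
control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from .crick import CrickParams, CANONICAL_DIMER, build_helix, PHASE_OF_A, HEPTAD
from .structures import Atom, Residue, Segment, SegmentConfig, Structure
from .knots import make_parametric_knot  # re-exported fixture generator

__all__ = ["SegmentSpec", "TopologySpec", "OrigamiModel", "BuildError",
           "build_origami", "default_topology", "dimer_structure",
           "load_topology", "make_parametric_knot"]

CA_CA = 3.8  # Å, consecutive Cα distance used for linker capacity checks

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "E": "GLU", "Q": "GLN", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# heptad-informed pseudo-sequence for built helices
_HEPTAD_RESIDUE = {"a": "LEU", "b": "ALA", "c": "ALA", "d": "LEU",
                   "e": "GLU", "f": "ALA", "g": "LYS"}


class BuildError(ValueError):
    """Raised for infeasible or inconsistent topology specifications."""


@dataclass
class SegmentSpec:
    segment_id: str
    cc_name: str
    n_res: int
    partner_id: str
    orientation: str = "parallel"
    heptad_start: str = "a"

    def __post_init__(self) -> None:
        if self.n_res < 7:
            raise BuildError(f"segment {self.segment_id}: need n_res >= 7")
        if self.orientation not in ("parallel", "antiparallel"):
            raise BuildError(f"segment {self.segment_id}: bad orientation")


@dataclass
class TopologySpec:
    """Chain-ordered segments, linkers, edge assignment and packing sides."""

    segments: list[SegmentSpec]
    linkers: list[str]
    edge_assignment: dict[str, int]
    inner_outer: dict[str, str] = field(default_factory=dict)
    plane_crossing: bool = True

    def __post_init__(self) -> None:
        ids = [s.segment_id for s in self.segments]
        if len(set(ids)) != len(ids):
            raise BuildError("duplicate segment ids")
        if len(self.linkers) != len(self.segments) - 1:
            raise BuildError(
                f"need {len(self.segments) - 1} linkers, got {len(self.linkers)}")
        by_id = {s.segment_id: s for s in self.segments}
        for s in self.segments:
            p = by_id.get(s.partner_id)
            if p is None or p.partner_id != s.segment_id:
                raise BuildError(f"partner relation broken at {s.segment_id}")
            if s.orientation != "parallel":
                raise BuildError("a closed triangle requires parallel CC dimers")
        edges: dict[int, list[str]] = {}
        for sid, e in self.edge_assignment.items():
            edges.setdefault(e, []).append(sid)
        if sorted(edges) != [0, 1, 2] or any(len(v) != 2 for v in edges.values()):
            raise BuildError("edge assignment must place exactly 2 segments "
                             "on each of edges 0, 1, 2")
        for e, (a, b) in edges.items():
            if by_id[a].partner_id != b:
                raise BuildError(f"edge {e}: segments {a},{b} are not a dimer")
        for sid in self.inner_outer.values():
            if sid not in ("inner", "outer"):
                raise BuildError("inner_outer flags must be 'inner' or 'outer'")


@dataclass
class OrigamiModel:
    structure: Structure
    segment_config: SegmentConfig
    topology: TopologySpec
    edge_vertices: np.ndarray  # (3,3) triangle vertices used internally


def default_topology(edge_lengths: Sequence[float] = (47.0, 34.0, 47.0),
                     linker: str = "GSG",
                     rise: float = CANONICAL_DIMER.rise,
                     plane_crossing: bool = True) -> TopologySpec:
    """Paper-like triangle: chain order P1, GCN-a, P4, P2, GCN-b, P3.

    Edge 0 carries P1:P2, edge 1 the GCN homodimer, edge 2 P3:P4.  Segment
    lengths are chosen so that the measured (window-trimmed) dimer axis
    length equals the requested edge length.
    """
    order = [("P1", "P1", 0, "P2"), ("GCN-a", "GCN", 1, "GCN-b"),
             ("P4", "P4", 2, "P3"), ("P2", "P2", 0, "P1"),
             ("GCN-b", "GCN", 1, "GCN-a"), ("P3", "P3", 2, "P4")]
    segments = []
    edge_assignment = {}
    inner_outer = {}
    for i, (sid, cc, edge, partner) in enumerate(order):
        n = round(edge_lengths[edge] / rise) + 7
        segments.append(SegmentSpec(sid, cc, n, partner))
        edge_assignment[sid] = edge
        if plane_crossing:
            # segments alternate inner/outer along the chain (knotted fold)
            inner_outer[sid] = "inner" if i % 2 == 0 else "outer"
        else:
            # planar control: first pass forms the inner triangle, second
            # pass the outer one — nested rings, topologically trivial
            inner_outer[sid] = "inner" if i < 3 else "outer"
    return TopologySpec(segments=segments, linkers=[linker] * 5,
                        edge_assignment=edge_assignment,
                        inner_outer=inner_outer, plane_crossing=plane_crossing)


def _triangle_vertices(sides: Sequence[float]) -> np.ndarray:
    """Vertices V0,V1,V2 of a triangle with |V0V1|=s0, |V1V2|=s1, |V2V0|=s2."""
    s0, s1, s2 = sides
    if s0 + s1 <= s2 or s1 + s2 <= s0 or s2 + s0 <= s1:
        raise BuildError(f"edge lengths {sides} violate the triangle inequality")
    x = (s0**2 + s2**2 - s1**2) / (2 * s0)
    y2 = s2**2 - x**2
    if y2 <= 0:
        raise BuildError(f"degenerate triangle for sides {sides}")
    return np.array([[0.0, 0.0, 0.0], [s0, 0.0, 0.0], [x, math.sqrt(y2), 0.0]])


def build_origami(topology: TopologySpec,
                  dimer_params: Optional[dict[str, CrickParams]] = None,
                  edge_lengths: Sequence[float] = (47.0, 34.0, 47.0),
                  jitter: float = 0.0, seed: int = 0,
                  chain_id: str = "A") -> OrigamiModel:
    """Build a single-chain Cα model of a triangular CC origami.

    ``dimer_params`` maps cc_name to the Crick parameters of that dimer
    (defaults to canonical values); ``edge_lengths`` are the target measured
    axis lengths of the three edges.  ``jitter`` adds seeded Gaussian noise
    (Å) to every Cα for robustness experiments.
    """
    dimer_params = dimer_params or {}
    rng = np.random.default_rng(seed)
    by_id = {s.segment_id: s for s in topology.segments}

    def params_of(seg: SegmentSpec) -> CrickParams:
        return dimer_params.get(seg.cc_name, CANONICAL_DIMER)

    # Helix spans are sized so the window-7 trimmed dimer axis equals the
    # requested edge length; segments are inset from the vertices so that
    # termini of consecutive segments do not collide there.
    inset = 5.5
    spans = []
    sides = []
    for e in range(3):
        segs = [s for s in topology.segments if topology.edge_assignment[s.segment_id] == e]
        n = min(s.n_res for s in segs)
        if n < 9:
            raise BuildError(f"edge {e}: segments too short for a measurable axis")
        span = edge_lengths[e] * (n - 1) / (n - 7)
        spans.append(span)
        sides.append(span + 2 * inset)
    verts = _triangle_vertices(sides)
    centroid = verts.mean(axis=0)

    # per-edge frames
    edge_dir, edge_out = [], []
    for e in range(3):
        v0, v1 = verts[e], verts[(e + 1) % 3]
        d = (v1 - v0) / np.linalg.norm(v1 - v0)
        mid = 0.5 * (v0 + v1)
        out = mid - centroid
        out -= (out @ d) * d
        out /= np.linalg.norm(out)
        edge_dir.append(d)
        edge_out.append(out)
    zhat = np.array([0.0, 0.0, 1.0])

    chain_res: list[Residue] = []
    seg_ranges: dict[str, tuple[int, int]] = {}
    seq_id = 0
    psi = 90.0  # current tube phase (deg): 0 = outer, 90 = above plane
    prev_end: Optional[np.ndarray] = None

    for idx, seg in enumerate(topology.segments):
        e = topology.edge_assignment[seg.segment_id]
        p = params_of(seg)
        rho = p.r0
        n = seg.n_res
        v0, v1 = verts[e], verts[(e + 1) % 3]
        t = np.linspace(0.0, 1.0, n)
        # chain termini get an extra along-edge shift so start and end,
        # which revisit the same vertex, do not meet in space
        lo = inset
        edge_pts = v0 + np.outer(lo + t * spans[e], edge_dir[e])

        side = topology.inner_outer.get(seg.segment_id, "inner" if idx % 2 == 0 else "outer")
        if topology.plane_crossing:
            mid_target = 180.0 if side == "inner" else 0.0
            # sweep ±180° choosing the direction that hits the requested side
            for delta in (180.0, -180.0):
                if np.isclose((psi + delta / 2.0) % 360.0, mid_target % 360.0):
                    break
            else:
                raise BuildError(
                    f"segment {seg.segment_id}: side {side!r} unreachable from "
                    f"tube phase {psi:.0f}° — flags must alternate for a closed sweep")
            # chain termini revisit the start vertex; trimming the first
            # and last sweeps by a small phase keeps them apart in space
            trim = math.copysign(25.0, delta)
            start = psi + (trim if idx == 0 else 0.0)
            end = psi + delta - (trim if idx == len(topology.segments) - 1 else 0.0)
            psi_t = start + (end - start) * t
            psi = float((psi + delta) % 360.0)
        else:
            psi_t = np.full(n, 180.0 if side == "inner" else 0.0)
        rad = np.radians(psi_t)
        offsets = np.outer(np.cos(rad), edge_out[e]) + np.outer(np.sin(rad), zhat)
        axis = edge_pts + rho * offsets

        # minor helix around the (possibly curved) axis; b = 0 points away
        # from the partner helix (radially out of the dimer tube)
        tang = np.gradient(axis, axis=0)
        tang /= np.linalg.norm(tang, axis=1, keepdims=True)
        normal = offsets - np.einsum("ij,ij->i", offsets, tang)[:, None] * tang
        normal /= np.linalg.norm(normal, axis=1, keepdims=True)
        binorm = np.cross(tang, normal)
        # minor phase: residue 0 sits at the canonical phase of its heptad
        # letter, consecutive residues advance by w1
        start_letter = HEPTAD.index(seg.heptad_start)
        b = np.radians(PHASE_OF_A + _letter_phase_offset(seg.heptad_start)
                       + p.w1 * np.arange(n))
        ca = axis + p.r1 * (np.cos(b)[:, None] * normal + np.sin(b)[:, None] * binorm)

        if prev_end is not None:
            linker = topology.linkers[idx - 1]
            m = len(linker)
            gap = np.linalg.norm(ca[0] - prev_end)
            if gap > (m + 1) * CA_CA:
                raise BuildError(
                    f"linker {idx} ({linker!r}): span {gap:.1f} Å exceeds capacity "
                    f"{(m + 1) * CA_CA:.1f} Å")
            bulge_ref = centroid if topology.plane_crossing else None
            for j, pos in enumerate(_linker_path(prev_end, ca[0], m, bulge_ref)):
                seq_id += 1
                chain_res.append(Residue(seq_id, ONE_TO_THREE[linker[j]],
                                         [Atom("CA", "C", pos)]))
        first_id = seq_id + 1
        for i in range(n):
            letter = HEPTAD[(start_letter + i) % 7]
            seq_id += 1
            chain_res.append(Residue(seq_id, _HEPTAD_RESIDUE[letter],
                                     [Atom("CA", "C", ca[i])]))
        seg_ranges[seg.segment_id] = (first_id, seq_id)
        prev_end = ca[-1]

    # C-terminal cap: one extra residue stepping back toward the N terminus.
    # The designed chain is nearly cyclic (both termini revisit the start
    # vertex); the cap reproduces that closeness without fusing the ends.
    start_ca = chain_res[0].atoms[0].coord
    end_ca = chain_res[-1].atoms[0].coord
    gap = np.linalg.norm(start_ca - end_ca)
    if gap > 6.0:
        step = min(CA_CA, gap - 3.4)
        pos = end_ca + step * (start_ca - end_ca) / gap
        seq_id += 1
        chain_res.append(Residue(seq_id, "GLY", [Atom("CA", "C", pos)]))

    if jitter > 0:
        for r in chain_res:
            for a in r.atoms:
                a.coord = a.coord + rng.normal(0.0, jitter, 3)

    structure = Structure(chains={chain_id: chain_res})
    segments = {
        s.segment_id: Segment(s.segment_id, chain_id, *seg_ranges[s.segment_id],
                              cc_name=s.cc_name, heptad_start=s.heptad_start)
        for s in topology.segments
    }
    dimers = []
    seen = set()
    for s in topology.segments:
        key = frozenset((s.segment_id, s.partner_id))
        if key not in seen:
            seen.add(key)
            dimers.append((s.segment_id, s.partner_id, s.orientation))
    config = SegmentConfig(segments=segments, dimers=dimers)
    return OrigamiModel(structure=structure, segment_config=config,
                        topology=topology, edge_vertices=verts)


def _linker_path(p_end: np.ndarray, p_start: np.ndarray, m: int,
                 centroid=None, step: float = 3.2) -> np.ndarray:
    """Cα positions of m linker residues between two segment termini.

    Straight interpolation when the gap is wide enough; otherwise the path
    bulges outward (away from the triangle centroid) so that consecutive
    linker residues keep a realistic spacing instead of piling up.
    """
    if m == 0:
        return np.empty((0, 3))
    f = np.arange(1, m + 1) / (m + 1)
    straight = p_end + np.outer(f, p_start - p_end)
    gap = np.linalg.norm(p_start - p_end)
    target = (m + 1) * step
    if gap >= target:
        return straight
    # circular arc through both termini, bulging away from the centroid,
    # with the included angle chosen so the arc length matches the target
    # (uniform residue spacing along the arc)
    mid = 0.5 * (p_end + p_start)
    e_hat = (p_start - p_end) / max(gap, 1e-9)
    # bulge away from the reference point, or straight up when none is given
    u = (mid - centroid) if centroid is not None else np.array([0.0, 0.0, 1.0])
    u -= (u @ e_hat) * e_hat
    nrm = np.linalg.norm(u)
    u = u / nrm if nrm > 1e-6 else _any_perpendicular(e_hat)
    c = gap / 2.0
    lo_a, hi_a = 1e-6, np.pi - 1e-6
    for _ in range(60):
        phi = 0.5 * (lo_a + hi_a)
        if np.sin(phi) / phi > 2 * c / target:
            lo_a = phi
        else:
            hi_a = phi
    radius = c / np.sin(phi)
    center = mid - radius * np.cos(phi) * u
    alpha = -phi + 2 * phi * f
    return center + radius * (np.sin(alpha)[:, None] * e_hat
                              + np.cos(alpha)[:, None] * u)


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0]) if abs(v[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    w = np.cross(v, ref)
    return w / np.linalg.norm(w)


def _letter_phase_offset(letter: str) -> float:
    """Minor-phase offset (deg) of a heptad letter relative to position a."""
    return (HEPTAD.index(letter) * 360.0 * 2.0 / 7.0) % 360.0


def dimer_structure(params: CrickParams = CANONICAL_DIMER, n_res: int = 28,
                    orientation: str = "parallel", stubs: bool = True,
                    separation: float = 0.0) -> tuple[Structure, SegmentConfig]:
    """Two-chain ideal dimer Structure with pseudo side-chain stubs.

    Stub "CB" atoms sit 2.0 Å beyond the Cα, directed away from the minor
    helix axis, mimicking where a side-chain centroid points on an ideal
    helix.  ``separation`` adds extra inter-helix distance along x (used to
    build non-interacting controls).
    """
    chains = {}
    i = np.arange(n_res)
    for cid, phi0_extra in (("A", 0.0), ("B", 180.0)):
        from dataclasses import replace
        p = replace(params, phi0=params.phi0 + phi0_extra)
        ca = build_helix(p, n_res)
        a = np.radians(p.phi0 + p.w0 * i)
        axis = np.column_stack([p.r0 * np.cos(a), p.r0 * np.sin(a), p.rise * i])
        outward = ca - axis
        outward /= np.linalg.norm(outward, axis=1, keepdims=True)
        if cid == "B":
            if orientation == "antiparallel":
                flip = np.array([1.0, -1.0, -1.0])
                zoff = ca[-1, 2] + ca[0, 2]
                ca = ca * flip
                ca[:, 2] += zoff
                outward = outward * flip
            ca = ca + np.array([separation, 0.0, 0.0])
        residues = []
        for k in range(n_res):
            atoms = [Atom("CA", "C", ca[k])]
            if stubs:
                atoms.append(Atom("CB", "C", ca[k] + 2.0 * outward[k]))
            residues.append(Residue(k + 1, "LEU" if k % 7 in (0, 3) else "ALA", atoms))
        chains[cid] = residues
    st = Structure(chains=chains)
    config = SegmentConfig(
        segments={
            "A": Segment("A", "A", 1, n_res, cc_name="dimerA", heptad_start="a"),
            "B": Segment("B", "B", 1, n_res, cc_name="dimerB", heptad_start="a"),
        },
        dimers=[("A", "B", orientation)],
    )
    return st, config


def load_topology(path) -> TopologySpec:
    """Load a YAML topology spec (same field names as :class:`TopologySpec`)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    segments = [SegmentSpec(**d) for d in raw["segments"]]
    return TopologySpec(
        segments=segments,
        linkers=list(raw.get("linkers", [])),
        edge_assignment={k: int(v) for k, v in raw["edge_assignment"].items()},
        inner_outer=dict(raw.get("inner_outer", {})),
        plane_crossing=bool(raw.get("plane_crossing", True)),
    )
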