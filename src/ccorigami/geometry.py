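"""Origami-level geometry: edge lengths, cavity area, contact maps, vertices.

The triangle edges are CC dimers; an edge's axis is the moving-window
centroid polyline of the pooled dimer Cα trace, and its length the
distance between the first and last axis points.  The central cavity is
reported as a projected 2-D area (Å²) on the best-fit plane of the
structure, consistent with how such cavities are quoted for planar
origami folds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .structures import SegmentConfig, Structure, StructureError
from .coiledcoil import ca_trace_segment

__all__ = ["EdgeGeometry", "ContactRecord", "ContactMap", "edge_length",
           "cavity_area", "contact_map", "find_contacts", "vertex_report",
           "band_orientation"]

VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "MG": 1.73, "ZN": 1.39, "CA": 2.31, "NA": 2.27, "K": 2.75, "FE": 1.56,
}
PROBE_RADIUS = 1.4

AXIS_WINDOW = 7


@dataclass
class EdgeGeometry:
    dimer: tuple[str, str]
    axis: np.ndarray
    axis_length: float
    direction: np.ndarray
    edge_index: Optional[int] = None


@dataclass
class ContactRecord:
    res1: tuple[str, int, str]  # (chain, seq_id, atom name)
    res2: tuple[str, int, str]
    type: str                   # hbond | salt_bridge | proximity
    distance: float
    position1: Optional[str] = None  # heptad letters when a register is known
    position2: Optional[str] = None


@dataclass
class ContactMap:
    matrix: np.ndarray          # boolean, residue x residue
    distances: np.ndarray       # least inter-residue heavy-atom distance
    residues: list[tuple[str, int]]
    cutoff: float


def edge_length(structure: Structure, config: SegmentConfig,
                dimer: tuple[str, str], window: int = AXIS_WINDOW,
                edge_index: Optional[int] = None) -> EdgeGeometry:
    """Axis polyline and length of one CC dimer edge.

    The two segments are paired residue-by-residue (up to the shorter
    length) and the axis is the window-centroid polyline of the pooled Cα.
    """
    seg_a, seg_b = (config.segments[d] for d in dimer)
    ca_a = ca_trace_segment(structure, seg_a)
    ca_b = ca_trace_segment(structure, seg_b)
    n = min(len(ca_a), len(ca_b))
    if n < window + 1:
        raise StructureError(
            f"dimer {dimer}: {n} paired residues is shorter than the "
            f"{window}-residue axis window")
    orientation = next((o for a, b, o in config.dimers
                        if {a, b} == set(dimer)), "parallel")
    if orientation == "antiparallel":
        ca_b = ca_b[::-1]
    pooled = 0.5 * (ca_a[:n] + ca_b[:n])
    axis = np.array([pooled[i:i + window].mean(axis=0)
                     for i in range(n - window + 1)])
    vec = axis[-1] - axis[0]
    length = float(np.linalg.norm(vec))
    return EdgeGeometry(dimer=tuple(dimer), axis=axis, axis_length=length,
                        direction=vec / max(length, 1e-9), edge_index=edge_index)


def _best_fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    center = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - center)
    return center, vt  # rows: in-plane e1, e2, normal


def cavity_area(structure: Structure, grid: float = 0.5,
                probe: float = PROBE_RADIUS) -> float:
    """Projected area (Å²) of the internal cavity enclosed by the ring of
    segments, on the best-fit plane of all Cα.

    Heavy atoms are drawn as disks of radius vdW+probe on a square grid;
    the cavity is the empty region not connected to the exterior.  Returns
    0 (with no enclosed region) for non-ring structures.
    """
    ca_pts = []
    heavy = []
    radii = []
    for cid, res in structure.chains.items():
        for r in res:
            for a in r.atoms:
                if a.element == "H":
                    continue
                heavy.append(a.coord)
                radii.append(VDW_RADII.get(a.element.upper(), 1.7))
                if a.name == "CA":
                    ca_pts.append(a.coord)
    heavy = np.array(heavy)
    radii = np.array(radii)
    if len(ca_pts) < 3:
        raise StructureError("cavity_area needs at least 3 Cα atoms")
    center, frame = _best_fit_plane(np.array(ca_pts))
    uv = (heavy - center) @ frame[:2].T
    rad2d = radii + probe

    pad = rad2d.max() + 2 * grid
    lo = uv.min(axis=0) - pad
    hi = uv.max(axis=0) + pad
    nx, ny = (np.ceil((hi - lo) / grid).astype(int) + 1)
    xs = lo[0] + grid * np.arange(nx)
    ys = lo[1] + grid * np.arange(ny)
    occupied = np.zeros((nx, ny), dtype=bool)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    tree = cKDTree(np.column_stack([gx.ravel(), gy.ravel()]))
    for (u, v), r in zip(uv, rad2d):
        for idx in tree.query_ball_point([u, v], r):
            occupied.flat[idx] = True

    empty = ~occupied
    labels, _ = ndimage.label(empty)
    border = set(np.concatenate([labels[0, :], labels[-1, :],
                                 labels[:, 0], labels[:, -1]]))
    cavity_cells = 0
    for lab in np.unique(labels):
        if lab == 0 or lab in border:
            continue
        cavity_cells += int((labels == lab).sum())
    return cavity_cells * grid * grid


def _residue_list(structure: Structure):
    out = []
    for cid, res in structure.chains.items():
        for r in res:
            out.append((cid, r))
    return out


def contact_map(structure: Structure, cutoff: float = 10.0,
                min_separation: int = 2) -> ContactMap:
    """Residue-level contact map from least heavy-atom distances."""
    entries = _residue_list(structure)
    if len(entries) < 2:
        raise StructureError("contact map needs at least 2 residues")
    coords = []
    owner = []
    for k, (cid, r) in enumerate(entries):
        for a in r.atoms:
            if a.element != "H":
                coords.append(a.coord)
                owner.append(k)
    coords = np.array(coords)
    owner = np.array(owner)
    n = len(entries)
    dist = np.full((n, n), np.inf)
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(cutoff):
        a, b = owner[i], owner[j]
        if a == b:
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d < dist[a, b]:
            dist[a, b] = dist[b, a] = d
    sep = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    matrix = (dist <= cutoff) & (sep > min_separation)
    return ContactMap(matrix=matrix, distances=dist,
                      residues=[(cid, r.seq_id) for cid, r in entries],
                      cutoff=cutoff)


def band_orientation(cmap: ContactMap, config: SegmentConfig,
                     seg1: str, seg2: str) -> float:
    """Correlation of residue indices over contacts between two segments.

    Positive (≈+1) for bands parallel to the main diagonal — the signature
    of a parallel dimer; negative for cross-diagonal (vertex) features.
    """
    s1, s2 = config.segments[seg1], config.segments[seg2]
    ii, jj = [], []
    index = {key: k for k, key in enumerate(cmap.residues)}
    for (c1, r1), k1 in index.items():
        if c1 != s1.chain or not s1.first <= r1 <= s1.last:
            continue
        for (c2, r2), k2 in index.items():
            if c2 != s2.chain or not s2.first <= r2 <= s2.last:
                continue
            if cmap.matrix[k1, k2]:
                ii.append(r1)
                jj.append(r2)
    if len(ii) < 3 or len(set(ii)) < 2 or len(set(jj)) < 2:
        return float("nan")
    return float(np.corrcoef(ii, jj)[0, 1])


# ---------------------------------------------------------------------------
# hydrogen bonds and salt bridges (heavy-atom criteria, no hydrogens needed)

_SC_DONORS = {
    "ARG": ["NE", "NH1", "NH2"], "LYS": ["NZ"], "ASN": ["ND2"],
    "GLN": ["NE2"], "HIS": ["ND1", "NE2"], "SER": ["OG"], "THR": ["OG1"],
    "TYR": ["OH"], "TRP": ["NE1"], "CYS": ["SG"],
}
_SC_ACCEPTORS = {  # atom -> antecedent for the angle proxy
    "ASP": {"OD1": "CG", "OD2": "CG"}, "GLU": {"OE1": "CD", "OE2": "CD"},
    "ASN": {"OD1": "CG"}, "GLN": {"OE1": "CD"}, "SER": {"OG": "CB"},
    "THR": {"OG1": "CB"}, "TYR": {"OH": "CZ"}, "HIS": {"ND1": "CG", "NE2": "CD2"},
    "MET": {"SD": "CG"},
}
_CATIONIC = {"ARG": ["NH1", "NH2", "NE"], "LYS": ["NZ"], "HIS": ["ND1", "NE2"]}
_ANIONIC = {"ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"]}

HBOND_CUTOFF = 3.5
SALT_CUTOFF = 4.0


def _has_side_chains(structure: Structure) -> bool:
    for _, r in structure.residues():
        for a in r.atoms:
            if a.name not in ("N", "CA", "C", "O", "OXT"):
                return True
    return False


def find_contacts(structure: Structure, type: str = "hbond",
                  cutoff: Optional[float] = None,
                  config: Optional[SegmentConfig] = None,
                  registers: Optional[dict[str, dict[int, str]]] = None,
                  min_separation: int = 2) -> list[ContactRecord]:
    """Hydrogen bonds or salt bridges from heavy-atom geometry.

    hbond: donor–acceptor N/O distance ≤ 3.5 Å with a D–A–AA angle ≥ 90°
    standing in for the unobservable hydrogen.  salt_bridge: side-chain
    cationic N to anionic O distance ≤ 4.0 Å.
    """
    if type == "hbond":
        cutoff = cutoff or HBOND_CUTOFF
    elif type == "salt_bridge":
        cutoff = cutoff or SALT_CUTOFF
    else:
        raise ValueError(f"unknown contact type {type!r}")
    if not _has_side_chains(structure):
        raise StructureError(
            "hydrogen-bond/salt-bridge detection needs a full heavy-atom "
            "structure; this model is Cα-only")

    entries = _residue_list(structure)
    donors, acceptors = [], []  # (entry idx, atom, antecedent coord or None)
    for k, (cid, r) in enumerate(entries):
        for a in r.atoms:
            if type == "salt_bridge":
                if a.name in _CATIONIC.get(r.name, ()):
                    donors.append((k, a, None))
                if a.name in _ANIONIC.get(r.name, ()):
                    acceptors.append((k, a, None))
                continue
            if a.name == "N":
                donors.append((k, a, None))
            if a.name in _SC_DONORS.get(r.name, ()):
                donors.append((k, a, None))
            if a.name == "O" or a.name == "OXT":
                ante = r.atom("C")
                acceptors.append((k, a, ante.coord if ante else None))
            ante_name = _SC_ACCEPTORS.get(r.name, {}).get(a.name)
            if ante_name:
                ante = r.atom(ante_name)
                acceptors.append((k, a, ante.coord if ante else None))

    records = []
    seen = set()
    for kd, da, _ in donors:
        for ka, aa, ante in acceptors:
            if abs(kd - ka) <= min_separation:
                continue
            d = float(np.linalg.norm(da.coord - aa.coord))
            if d > cutoff:
                continue
            if type == "hbond" and ante is not None:
                v1 = da.coord - aa.coord
                v2 = ante - aa.coord
                cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-12)
                if np.degrees(np.arccos(np.clip(cosang, -1, 1))) < 90.0:
                    continue
            cd, rd = entries[kd]
            ca_, ra = entries[ka]
            key = (cd, rd.seq_id, da.name, ca_, ra.seq_id, aa.name)
            if key in seen:
                continue
            seen.add(key)
            rec = ContactRecord(
                res1=(cd, rd.seq_id, da.name), res2=(ca_, ra.seq_id, aa.name),
                type=type, distance=d)
            _annotate_positions(rec, config, registers)
            records.append(rec)
    return records


def _annotate_positions(rec: ContactRecord, config: Optional[SegmentConfig],
                        registers: Optional[dict[str, dict[int, str]]]) -> None:
    if config is None:
        return
    for attr, (cid, seq_id, _) in (("position1", rec.res1), ("position2", rec.res2)):
        sid = config.segment_of_residue(cid, seq_id)
        if sid is None:
            continue
        if registers and sid in registers and seq_id in registers[sid]:
            setattr(rec, attr, registers[sid][seq_id])
        else:
            seg = config.segments[sid]
            offset = (seq_id - seg.first) % 7
            from .crick import HEPTAD
            start = HEPTAD.index(seg.heptad_start)
            setattr(rec, attr, HEPTAD[(start + offset) % 7])


def vertex_report(structure: Structure, config: SegmentConfig,
                  proximity_cutoff: float = 6.0,
                  registers: Optional[dict[str, dict[int, str]]] = None,
                  ) -> dict[frozenset, list[ContactRecord]]:
    """Inter-dimer contacts grouped by vertex (unordered pair of dimers).

    On full heavy-atom structures the contacts are hydrogen bonds and salt
    bridges; on Cα-only models, proximity records within the cutoff.
    Intra-dimer contacts are excluded.
    """
    dimer_of: dict[str, frozenset] = {}
    for a, b, _ in config.dimers:
        dimer_of[a] = dimer_of[b] = frozenset((a, b))

    if _has_side_chains(structure):
        contacts = (find_contacts(structure, "hbond", config=config,
                                  registers=registers)
                    + find_contacts(structure, "salt_bridge", config=config,
                                    registers=registers))
    else:
        cmap = contact_map(structure, cutoff=proximity_cutoff)
        contacts = []
        n = len(cmap.residues)
        for i in range(n):
            for j in range(i + 1, n):
                if cmap.matrix[i, j]:
                    c1, r1 = cmap.residues[i]
                    c2, r2 = cmap.residues[j]
                    rec = ContactRecord(res1=(c1, r1, "CA"), res2=(c2, r2, "CA"),
                                        type="proximity",
                                        distance=float(cmap.distances[i, j]))
                    _annotate_positions(rec, config, registers)
                    contacts.append(rec)

    vertices: dict[frozenset, list[ContactRecord]] = {}
    for rec in contacts:
        s1 = config.segment_of_residue(rec.res1[0], rec.res1[1])
        s2 = config.segment_of_residue(rec.res2[0], rec.res2[1])
        if s1 is None or s2 is None:
            # linker residues: attribute to the nearest preceding segment
            s1 = s1 or _nearest_segment(config, rec.res1[0], rec.res1[1])
            s2 = s2 or _nearest_segment(config, rec.res2[0], rec.res2[1])
        if s1 is None or s2 is None:
            continue
        d1, d2 = dimer_of.get(s1), dimer_of.get(s2)
        if d1 is None or d2 is None or d1 == d2:
            continue
        vertices.setdefault(frozenset((d1, d2)), []).append(rec)
    return vertices


def _nearest_segment(config: SegmentConfig, chain: str, seq_id: int) -> Optional[str]:
    best, best_gap = None, None
    for sid, seg in config.segments.items():
        if seg.chain != chain:
            continue
        gap = min(abs(seq_id - seg.first), abs(seq_id - seg.last))
        if best_gap is None or gap < best_gap:
            best, best_gap = sid, gap
    return best
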