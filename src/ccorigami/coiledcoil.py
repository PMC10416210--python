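"""Heptad registers, knobs-into-holes packing, and helix content.

Knobs-into-holes (KIH) is the signature coiled-coil packing: a side chain
("knob") of one helix inserts between four side chains ("hole") of the
partner helix.  Detection follows the SOCKET convention operationally:
side-chain centers within a packing cutoff (default 7 Å) of at least four
partner side-chain centers are knobs, and the four nearest partner
residues form the hole.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .crick import HEPTAD, PHASE_OF_A, fit_crick
from .structures import Residue, Segment, SegmentConfig, Structure, StructureError, ca_trace

__all__ = ["KihContact", "HeptadRegister", "detect_kih", "assign_register",
           "helicity", "side_chain_center"]

_BACKBONE = {"N", "CA", "C", "O", "OXT"}


@dataclass
class KihContact:
    knob_segment: str
    knob_residue: int
    hole_segment: str
    hole_residues: tuple[int, ...]
    packing_cutoff: float
    knob_position: Optional[str] = None  # heptad letter, annotated post hoc


@dataclass
class HeptadRegister:
    segment_id: str
    positions: dict[int, str]  # seq_id -> letter a..g

    def as_string(self) -> str:
        return "".join(self.positions[k] for k in sorted(self.positions))


def side_chain_center(residue: Residue) -> Optional[np.ndarray]:
    """Centroid of side-chain heavy atoms; Gly and stripped residues fall
    back to a virtual Cβ along the Cα direction when possible, else None."""
    side = [a.coord for a in residue.atoms
            if a.name not in _BACKBONE and a.element != "H"]
    if side:
        return np.mean(side, axis=0)
    return None


def _segment_residues(structure: Structure, seg: Segment) -> list[Residue]:
    return [r for r in structure.chains[seg.chain]
            if seg.first <= r.seq_id <= seg.last]


def detect_kih(structure: Structure, config: SegmentConfig,
               dimer: tuple[str, str], packing_cutoff: float = 7.0,
               min_hole: int = 4) -> list[KihContact]:
    """Knobs-into-holes contacts between the two segments of a dimer.

    Requires side-chain heavy atoms (at least Cβ); Cα-only input raises a
    capability error — use register-by-phase instead for such models.
    """
    contacts: list[KihContact] = []
    seg_a, seg_b = (config.segments[d] for d in dimer)
    res_a = _segment_residues(structure, seg_a)
    res_b = _segment_residues(structure, seg_b)
    centers_a = [(r.seq_id, side_chain_center(r)) for r in res_a]
    centers_b = [(r.seq_id, side_chain_center(r)) for r in res_b]
    if all(c is None for _, c in centers_a + centers_b):
        raise StructureError(
            "knobs-into-holes needs side-chain heavy atoms (Cβ at minimum); "
            "for Cα-only models assign the register from the Crick phase")

    for (knob_seg, knob_centers, hole_seg, hole_centers) in (
            (seg_a, centers_a, seg_b, centers_b),
            (seg_b, centers_b, seg_a, centers_a)):
        hole_ids = [i for i, c in hole_centers if c is not None]
        hole_xyz = np.array([c for _, c in hole_centers if c is not None])
        if len(hole_xyz) < min_hole:
            continue
        for seq_id, center in knob_centers:
            if center is None:
                continue
            dist = np.linalg.norm(hole_xyz - center, axis=1)
            within = np.where(dist <= packing_cutoff)[0]
            if len(within) >= min_hole:
                nearest = within[np.argsort(dist[within])][:min_hole]
                contacts.append(KihContact(
                    knob_segment=knob_seg.segment_id, knob_residue=seq_id,
                    hole_segment=hole_seg.segment_id,
                    hole_residues=tuple(int(hole_ids[k]) for k in sorted(nearest)),
                    packing_cutoff=packing_cutoff))
    return contacts


def assign_register(structure: Structure, config: SegmentConfig, segment_id: str,
                    method: str = "crick_phase",
                    packing_cutoff: float = 7.0) -> HeptadRegister:
    """Periodic a–g heptad labeling of one segment.

    ``kih``: knob residues are anchored to positions a/d — the knob spacing
    pattern (3,4,3,4,...) fixes the register uniquely.  ``crick_phase``: the
    fitted minor-helix phase of each residue is binned to the canonical
    phase of its heptad letter.  Both agree on ideal dimers.
    """
    seg = config.segments[segment_id]
    residues = _segment_residues(structure, seg)
    seq_ids = [r.seq_id for r in residues]
    n = len(seq_ids)

    if method == "kih":
        dimer = config.dimer_of(segment_id)
        if dimer is None:
            raise StructureError(f"segment {segment_id} has no dimer partner")
        contacts = detect_kih(structure, config, (segment_id, dimer[0]),
                              packing_cutoff=packing_cutoff)
        knob_idx = [seq_ids.index(c.knob_residue) for c in contacts
                    if c.knob_segment == segment_id]
        if not knob_idx:
            raise StructureError(f"no knobs found on segment {segment_id}")
        # choose the offset placing most knobs on positions a (0) and d (3)
        scores = [sum((k + off) % 7 in (0, 3) for k in knob_idx) for off in range(7)]
        best = max(scores)
        offset = scores.index(best)  # ties: lowest offset
        letters = {sid: HEPTAD[(i + offset) % 7] for i, sid in enumerate(seq_ids)}
        return HeptadRegister(segment_id, letters)

    if method == "crick_phase":
        dimer = config.dimer_of(segment_id)
        chains = [np.asarray(ca_trace_segment(structure, seg))]
        if dimer is not None:
            partner = config.segments[dimer[0]]
            chains.append(np.asarray(ca_trace_segment(structure, partner)))
        fit = fit_crick(chains, orientation=dimer[1] if dimer else "parallel")
        p = fit.params
        letters = {}
        for i, sid in enumerate(seq_ids):
            phase = (p.phi1 + p.w1 * i) % 360.0
            # nearest canonical letter phase; ties resolved toward earlier letters
            diffs = [(_ang_dist(phase, PHASE_OF_A + 360.0 * 2.0 / 7.0 * k), k)
                     for k in range(7)]
            letters[sid] = HEPTAD[min(diffs)[1]]
        return HeptadRegister(segment_id, letters)

    raise ValueError(f"unknown register method {method!r}")


def _ang_dist(x: float, y: float) -> float:
    return abs((x - y + 180.0) % 360.0 - 180.0)


def ca_trace_segment(structure: Structure, seg: Segment) -> np.ndarray:
    pts = [r.ca.coord for r in _segment_residues(structure, seg) if r.ca is not None]
    return np.array(pts, dtype=float)


def helicity(structure: Structure, chain: str) -> float:
    """Fraction of residues in helical conformation, from the Cα trace.

    A residue i is helical when the i→i+3 Cα distance lies in [4.5, 6.0] Å
    and the local virtual twist angle lies in [85°, 115°] — an operational
    Cα-only criterion, not DSSP.
    """
    coords = ca_trace(structure, chain).coords
    n = len(coords)
    if n < 4:
        raise StructureError("helicity needs at least 4 residues")
    helical = np.zeros(n, dtype=bool)
    for i in range(n - 3):
        window = coords[i:i + 4]
        d13 = np.linalg.norm(window[3] - window[0])
        if not 4.5 <= d13 <= 6.0:
            continue
        # local axis from the window; twist = angle between consecutive
        # Cα–Cα bonds projected perpendicular to that axis (≈100° in α-helix)
        centered = window - window.mean(axis=0)
        _, _, vt = np.linalg.svd(centered)
        axis = vt[0]
        bonds = np.diff(window, axis=0)
        perp = bonds - np.outer(bonds @ axis, axis)
        norms = np.linalg.norm(perp, axis=1)
        if norms.min() < 1e-9:
            continue
        perp /= norms[:, None]
        angles = [np.degrees(np.arccos(np.clip(perp[j] @ perp[j + 1], -1, 1)))
                  for j in range(2)]
        if all(85.0 <= a <= 115.0 for a in angles):
            helical[i:i + 4] |= True
    return float(helical.sum() / n)
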