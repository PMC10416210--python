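"""Crystal packing in space group P1: lattice neighbors, buried surface
area, unique interfaces, Matthews coefficient and solvent content.

In P1 the only symmetry operations are lattice translations, so every
crystal neighbor of the single molecule in the asymmetric unit is a copy
translated by an integer combination of the cell vectors, and every
interface appears twice (at t and −t, seen from the two partners).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .geometry import VDW_RADII, PROBE_RADIUS, find_contacts, _has_side_chains
from .structures import SegmentConfig, Structure, UnitCell, StructureError

__all__ = ["LatticeNeighbor", "InterfaceCluster", "PackingSummary", "sasa",
           "lattice_neighbors", "unique_interfaces", "packing_summary",
           "contact_position_profile"]

MATTHEWS_CONST = 1.23  # Å³/Da; solvent fraction = 1 − 1.23/Vm


@dataclass
class LatticeNeighbor:
    translation: tuple[int, int, int]
    buried_area: float
    contact_residues_central: set = field(default_factory=set)
    contact_residues_neighbor: set = field(default_factory=set)


@dataclass
class InterfaceCluster:
    representative: tuple[int, int, int]
    members: list[tuple[int, int, int]]
    buried_area: float
    heterologous: bool


@dataclass
class PackingSummary:
    n_neighbors: int
    n_unique_interfaces: int
    total_buried: float
    buried_fraction: float
    matthews_vm: float
    solvent_fraction: float


def _heavy_atoms(structure: Structure) -> tuple[np.ndarray, np.ndarray]:
    coords, radii, missing = [], [], set()
    for _, r in structure.residues():
        for a in r.atoms:
            if a.element == "H":
                continue
            key = a.element.upper()
            if key not in VDW_RADII:
                missing.add(a.element)
                continue
            coords.append(a.coord)
            radii.append(VDW_RADII[key])
    if missing:
        raise StructureError(f"no van der Waals radius for elements {sorted(missing)}")
    return np.array(coords), np.array(radii)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack([np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi), np.cos(phi)])


def sasa(structure: Structure | tuple[np.ndarray, np.ndarray],
         probe: float = PROBE_RADIUS, n_sphere_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface areas (Shrake–Rupley).

    Deterministic for a fixed point count; pass a ``(coords, radii)`` pair
    to bypass structure bookkeeping.
    """
    if isinstance(structure, Structure):
        coords, radii = _heavy_atoms(structure)
    else:
        coords, radii = (np.asarray(x, dtype=float) for x in structure)
    n = len(coords)
    if n == 0:
        raise StructureError("no heavy atoms")
    ext = radii + probe
    unit = _sphere_points(n_sphere_points)
    tree = cKDTree(coords)
    areas = np.empty(n)
    max_ext = ext.max()
    for i in range(n):
        pts = coords[i] + ext[i] * unit
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in tree.query_ball_point(coords[i], ext[i] + max_ext):
            if j == i:
                continue
            accessible &= np.sum((pts - coords[j]) ** 2, axis=1) > ext[j] ** 2
            if not accessible.any():
                break
        areas[i] = 4.0 * np.pi * ext[i] ** 2 * accessible.mean()
    return areas


def _translated_coords(coords: np.ndarray, cell: UnitCell,
                       t: tuple[int, int, int]) -> np.ndarray:
    vecs = cell.vectors()
    shift = t[0] * vecs[0] + t[1] * vecs[1] + t[2] * vecs[2]
    return coords + shift


def lattice_neighbors(structure: Structure, cell: Optional[UnitCell] = None,
                      search_range: int = 1, area_threshold: float = 10.0,
                      probe: float = PROBE_RADIUS,
                      n_sphere_points: int = 960) -> list[LatticeNeighbor]:
    """Lattice-translation neighbors with nonzero buried surface area.

    Only P1 is supported: neighbors are the molecule translated by
    i·a + j·b + k·c for all nonzero (i,j,k) in the search range; a
    neighbor is kept when the buried area [sasa(A)+sasa(B)−sasa(A∪B)]/2
    exceeds the threshold.
    """
    cell = cell or structure.cell
    if cell is None:
        raise StructureError("lattice analysis needs a unit cell")
    sg = cell.space_group.replace(" ", "").upper()
    if sg not in ("P1", "P 1"):
        raise StructureError(
            f"space group {cell.space_group!r} unsupported: only P1 "
            "(pure lattice translations) is implemented")
    coords, radii = _heavy_atoms(structure)
    iso = sasa((coords, radii), probe=probe, n_sphere_points=n_sphere_points)
    iso_total = iso.sum()
    # residue bookkeeping for interface composition
    res_of_atom = []
    for cid, r in structure.residues():
        for a in r.atoms:
            if a.element != "H" and a.element.upper() in VDW_RADII:
                res_of_atom.append((cid, r.seq_id))

    neighbors = []
    rng = range(-search_range, search_range + 1)
    diameter = 2 * (radii.max() + probe)
    for t in itertools.product(rng, rng, rng):
        if t == (0, 0, 0):
            continue
        other = _translated_coords(coords, cell, t)
        # quick reject: bounding-sphere style distance gate
        tree_a = cKDTree(coords)
        dmin, _ = tree_a.query(other, k=1)
        if dmin.min() > diameter:
            continue
        pair_coords = np.vstack([coords, other])
        pair_radii = np.concatenate([radii, radii])
        pair = sasa((pair_coords, pair_radii), probe=probe,
                    n_sphere_points=n_sphere_points)
        buried = (iso_total * 2 - pair.sum()) / 2.0
        if buried <= area_threshold:
            continue
        # contact residues: atoms within vdW+2*probe of the partner
        tree_b = cKDTree(other)
        cutoff = 2 * (radii.max() + probe)
        central_res, neigh_res = set(), set()
        for ia, js in enumerate(tree_a.query_ball_tree(tree_b, cutoff)):
            for jb in js:
                if (np.linalg.norm(coords[ia] - other[jb])
                        <= radii[ia] + radii[jb] + 2 * probe):
                    central_res.add(res_of_atom[ia])
                    neigh_res.add(res_of_atom[jb])
        neighbors.append(LatticeNeighbor(
            translation=t, buried_area=float(buried),
            contact_residues_central=central_res,
            contact_residues_neighbor=neigh_res))
    return neighbors


def unique_interfaces(neighbors: Sequence[LatticeNeighbor]) -> list[InterfaceCluster]:
    """Cluster P1 neighbors into unique interfaces by pairing t with −t.

    An interface is heterologous when the two contacting surface patches
    (residue sets on the two sides) differ.
    """
    by_t = {n.translation: n for n in neighbors}
    clusters = []
    done = set()
    for t, n in sorted(by_t.items()):
        if t in done:
            continue
        neg = tuple(-x for x in t)
        members = [t] + ([neg] if neg in by_t else [])
        done.update(members)
        hetero = n.contact_residues_central != n.contact_residues_neighbor
        clusters.append(InterfaceCluster(
            representative=t, members=members,
            buried_area=n.buried_area, heterologous=hetero))
    return clusters


def packing_summary(structure: Structure, cell: Optional[UnitCell] = None,
                    mass: Optional[float] = None,
                    neighbors: Optional[Sequence[LatticeNeighbor]] = None,
                    z: int = 1, **kwargs) -> PackingSummary:
    """Per-molecule packing summary: buried area, Matthews Vm, solvent
    fraction (1 − 1.23/Vm with Vm in Å³/Da)."""
    cell = cell or structure.cell
    if cell is None:
        raise StructureError("packing summary needs a unit cell")
    if mass is None or mass <= 0:
        raise StructureError("packing summary needs a positive molecular mass")
    if neighbors is None:
        neighbors = lattice_neighbors(structure, cell, **kwargs)
    coords, radii = _heavy_atoms(structure)
    iso_total = float(sasa((coords, radii)).sum())
    total_buried = float(sum(n.buried_area for n in neighbors))
    vm = cell.volume / (mass * z)
    solvent = 1.0 - MATTHEWS_CONST / vm
    if vm <= MATTHEWS_CONST:
        import warnings
        warnings.warn(f"Matthews coefficient {vm:.2f} Å³/Da is physically "
                      "implausible (≤1.23): check cell, Z or mass")
    return PackingSummary(
        n_neighbors=len(neighbors),
        n_unique_interfaces=len(unique_interfaces(neighbors)),
        total_buried=total_buried,
        buried_fraction=total_buried / iso_total if iso_total > 0 else 0.0,
        matthews_vm=float(vm), solvent_fraction=float(solvent))


def contact_position_profile(structure: Structure,
                             neighbors: Sequence[LatticeNeighbor],
                             config: SegmentConfig,
                             cell: Optional[UnitCell] = None,
                             registers: Optional[dict] = None) -> dict[str, int]:
    """Crystal-contact hydrogen bonds tallied by heptad position class.

    Classes: exposed b/c/f, flanking e/g, core a/d.  Every inter-molecule
    hydrogen bond between the central molecule and each lattice neighbor
    contributes the class of the central molecule's residue.
    """
    cell = cell or structure.cell
    if cell is None:
        raise StructureError("needs a unit cell")
    if not _has_side_chains(structure):
        raise StructureError("position profile needs a full heavy-atom structure")
    profile = {"b/c/f": 0, "e/g": 0, "a/d": 0}
    class_of = {"b": "b/c/f", "c": "b/c/f", "f": "b/c/f",
                "e": "e/g", "g": "e/g", "a": "a/d", "d": "a/d"}
    n_chain_res = sum(len(v) for v in structure.chains.values())
    for nb in neighbors:
        combined = _merge_with_translated(structure, cell, nb.translation)
        hbonds = find_contacts(combined, "hbond", config=config,
                               registers=registers, min_separation=0)
        for rec in hbonds:
            # keep only bonds spanning the two copies
            c1 = rec.res1[0].endswith("*")
            c2 = rec.res2[0].endswith("*")
            if c1 == c2:
                continue
            central = rec.res2 if c1 else rec.res1
            pos = rec.position2 if c1 else rec.position1
            if pos is None:
                sid = config.segment_of_residue(central[0], central[1])
                if sid is None:
                    continue
                seg = config.segments[sid]
                from .crick import HEPTAD
                pos = HEPTAD[(HEPTAD.index(seg.heptad_start)
                              + (central[1] - seg.first)) % 7]
            profile[class_of[pos]] += 1
    return profile


def _merge_with_translated(structure: Structure, cell: UnitCell,
                           t: tuple[int, int, int]) -> Structure:
    vecs = cell.vectors()
    shift = t[0] * vecs[0] + t[1] * vecs[1] + t[2] * vecs[2]
    copy = structure.translated(shift)
    chains = dict(structure.chains)
    for cid, res in copy.chains.items():
        chains[cid + "*"] = res
    return Structure(chains=chains, cell=cell)
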