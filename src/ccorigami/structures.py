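"""Macromolecular structure containers and I/O.

Thin domain layer over :mod:`gemmi`: structures are flattened to
chains -> residues -> heavy atoms (first model only), with the crystal
cell carried alongside when the file provides one.  Author residue
numbering is preserved throughout because all downstream reporting
refers to it.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence

import gemmi
import numpy as np
import yaml

__all__ = [
    "Atom",
    "Residue",
    "UnitCell",
    "Structure",
    "CaTrace",
    "Segment",
    "SegmentConfig",
    "StructureError",
    "read_structure",
    "write_structure",
    "ca_trace",
    "average_mass",
    "load_segment_config",
]


class StructureError(ValueError):
    """Raised for malformed files, empty selections and capacity limits."""


# ExPASy average isotopic residue masses (Da); a chain adds one water.
WATER_MASS = 18.015
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLU": "E", "GLN": "Q", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise StructureError(f"atom {self.name!r}: coordinate must be a finite 3-vector")
        if not self.element:
            raise StructureError(f"atom {self.name!r}: empty element symbol")


@dataclass
class Residue:
    seq_id: int
    name: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Optional[Atom]:
        return self.atom("CA")

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms if a.element != "H"], dtype=float)


@dataclass
class UnitCell:
    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    space_group: str = "P 1"
    z: int = 1

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise StructureError("unit cell lengths must be positive")
        if not all(0 < x < 180 for x in (self.alpha, self.beta, self.gamma)):
            raise StructureError("unit cell angles must lie in (0, 180) degrees")

    @property
    def volume(self) -> float:
        ca_, cb, cg = (np.cos(np.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return self.a * self.b * self.c * np.sqrt(
            1 - ca_**2 - cb**2 - cg**2 + 2 * ca_ * cb * cg
        )

    def vectors(self) -> np.ndarray:
        """Real-space cell vectors as rows (standard PDB orthogonalization)."""
        cell = gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)
        m = cell.orth.mat
        return np.array(m.tolist(), dtype=float).T  # rows = a, b, c


@dataclass
class Structure:
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    cell: Optional[UnitCell] = None

    def __post_init__(self) -> None:
        for cid, residues in self.chains.items():
            ids = [r.seq_id for r in residues]
            if any(b <= a for a, b in zip(ids, ids[1:])):
                raise StructureError(f"chain {cid}: residue seq_ids must strictly increase")

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for res in self.chains.values() for r in res)

    def residues(self, chain: Optional[str] = None) -> Iterator[tuple[str, Residue]]:
        chains = [chain] if chain is not None else list(self.chains)
        for cid in chains:
            for r in self.chains[cid]:
                yield cid, r

    def get_residue(self, chain: str, seq_id: int) -> Residue:
        for r in self.chains[chain]:
            if r.seq_id == seq_id:
                return r
        raise KeyError(f"residue {seq_id} not in chain {chain}")

    def all_heavy_coords(self) -> np.ndarray:
        pts = [a.coord for res in self.chains.values() for r in res
               for a in r.atoms if a.element != "H"]
        if not pts:
            raise StructureError("structure has no heavy atoms")
        return np.array(pts, dtype=float)

    def sequence(self, chain: str) -> str:
        return "".join(THREE_TO_ONE.get(r.name, "X") for r in self.chains[chain])

    def translated(self, shift: Sequence[float]) -> "Structure":
        shift = np.asarray(shift, dtype=float)
        chains = {
            cid: [
                Residue(r.seq_id, r.name,
                        [Atom(a.name, a.element, a.coord + shift, a.occupancy, a.bfactor)
                         for a in r.atoms])
                for r in res
            ]
            for cid, res in self.chains.items()
        }
        return Structure(chains=chains, cell=self.cell)


@dataclass
class CaTrace:
    """Ordered Cα coordinates for one chain, with bookkeeping of skipped residues."""

    coords: np.ndarray
    seq_ids: list[int]
    skipped: list[int]

    def __len__(self) -> int:
        return len(self.seq_ids)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.coords, dtype=dtype)


def _infer_format(path: str, fmt: Optional[str]) -> str:
    if fmt:
        return fmt
    low = str(path).lower()
    if low.endswith((".cif", ".mmcif")):
        return "mmcif"
    return "pdb"


_WATER_NAMES = {"HOH", "WAT", "DOD"}


def read_structure(path: str | os.PathLike, format: Optional[str] = None,
                   keep_hydrogens: bool = False, keep_waters: bool = False) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Only the first model is kept.  Alternate conformers are collapsed to the
    highest-occupancy copy; hydrogens and waters are dropped unless requested.
    """
    fmt = _infer_format(path, format)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise StructureError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:  # gemmi parse failures
        raise StructureError(f"cannot parse {path} as {fmt}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: no coordinate models found")
    st.remove_empty_chains()

    model = st[0]
    chains: dict[str, list[Residue]] = {}
    for ch in model:
        residues: list[Residue] = []
        for res in ch:
            if not keep_waters and res.name in _WATER_NAMES:
                continue
            # collapse altlocs: keep highest occupancy per atom name
            best: dict[str, gemmi.Atom] = {}
            for at in res:
                if not keep_hydrogens and at.element.is_hydrogen:
                    continue
                prev = best.get(at.name)
                if prev is None or at.occ > prev.occ:
                    best[at.name] = at
            if not best:
                continue
            atoms = [
                Atom(at.name, at.element.name,
                     np.array([at.pos.x, at.pos.y, at.pos.z]), at.occ, at.b_iso)
                for at in best.values()
            ]
            residues.append(Residue(res.seqid.num, res.name, atoms))
        if residues:
            # enforce strictly increasing numbering; gemmi preserves file order
            chains[ch.name] = residues
    if not chains:
        raise StructureError(f"{path}: file contains no coordinates")

    cell = None
    if st.cell and st.cell.a > 1.0 and not (
        st.cell.a == st.cell.b == st.cell.c == 1.0
    ):
        cell = UnitCell(st.cell.a, st.cell.b, st.cell.c,
                        st.cell.alpha, st.cell.beta, st.cell.gamma,
                        st.spacegroup_hm or "P 1")
    return Structure(chains=chains, cell=cell)


def write_structure(structure: Structure, path: str | os.PathLike,
                    format: str = "pdb") -> None:
    """Write a structure as fixed-width PDB (coordinates quantized to 0.001 Å)."""
    if format != "pdb":
        raise StructureError(f"unsupported output format {format!r}")
    if structure.n_atoms == 0:
        raise StructureError("refusing to write an empty structure")
    if structure.n_atoms > 99999:
        raise StructureError("PDB serial capacity exceeded (>99999 atoms)")

    st = gemmi.Structure()
    st.name = "model"
    if structure.cell is not None:
        c = structure.cell
        st.cell = gemmi.UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
        st.spacegroup_hm = c.space_group
    model = gemmi.Model("1")
    for cid, residues in structure.chains.items():
        ch = gemmi.Chain(cid)
        for r in residues:
            gr = gemmi.Residue()
            gr.name = r.name
            gr.seqid = gemmi.SeqId(r.seq_id, " ")
            for a in r.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coord)
                ga.occ = a.occupancy
                ga.b_iso = a.bfactor
                gr.add_atom(ga)
            ch.add_residue(gr)
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    text = st.make_pdb_string()
    if structure.cell is None:
        text = "\n".join(l for l in text.splitlines()
                         if not l.startswith(("CRYST1", "SCALE"))) + "\n"
    with open(path, "w") as fh:
        fh.write(text)


def ca_trace(structure: Structure, chain: str) -> CaTrace:
    """Cα coordinates of one chain in residue order; Cα-less residues are skipped."""
    if chain not in structure.chains:
        raise StructureError(f"chain {chain!r} not present "
                             f"(have {sorted(structure.chains)})")
    coords, ids, skipped = [], [], []
    for r in structure.chains[chain]:
        at = r.ca
        if at is None:
            skipped.append(r.seq_id)
        else:
            coords.append(at.coord)
            ids.append(r.seq_id)
    if not coords:
        raise StructureError(f"chain {chain!r} has no Cα atoms")
    return CaTrace(np.array(coords, dtype=float), ids, skipped)


def average_mass(sequence: str) -> float:
    """Average molecular mass (Da) of a polypeptide: residue masses + one water."""
    mass = WATER_MASS
    for ch in sequence:
        try:
            mass += AVERAGE_RESIDUE_MASS[ch.upper()]
        except KeyError:
            raise StructureError(f"unknown amino-acid letter {ch!r}") from None
    return mass


# ---------------------------------------------------------------------------
# segment configuration


@dataclass
class Segment:
    segment_id: str
    chain: str
    first: int
    last: int
    cc_name: str
    heptad_start: str = "a"

    def __post_init__(self) -> None:
        if self.last < self.first:
            raise StructureError(f"segment {self.segment_id}: last < first")
        if self.heptad_start not in "abcdefg":
            raise StructureError(f"segment {self.segment_id}: heptad_start must be a–g")

    @property
    def n_res(self) -> int:
        return self.last - self.first + 1


@dataclass
class SegmentConfig:
    """Residue-range definitions of named CC segments plus their dimer pairing."""

    segments: dict[str, Segment]
    dimers: list[tuple[str, str, str]]  # (seg1, seg2, orientation)

    def __post_init__(self) -> None:
        by_chain: dict[str, list[Segment]] = {}
        for seg in self.segments.values():
            by_chain.setdefault(seg.chain, []).append(seg)
        for segs in by_chain.values():
            segs = sorted(segs, key=lambda s: s.first)
            for s1, s2 in zip(segs, segs[1:]):
                if s2.first <= s1.last:
                    raise StructureError(
                        f"segments {s1.segment_id} and {s2.segment_id} overlap")
        for a, b, orient in self.dimers:
            for sid in (a, b):
                if sid not in self.segments:
                    raise StructureError(f"dimer references unknown segment {sid!r}")
            if orient not in ("parallel", "antiparallel"):
                raise StructureError(f"dimer orientation {orient!r} invalid")

    def dimer_of(self, segment_id: str) -> Optional[tuple[str, str]]:
        for a, b, orient in self.dimers:
            if segment_id == a:
                return b, orient
            if segment_id == b:
                return a, orient
        return None

    def segment_of_residue(self, chain: str, seq_id: int) -> Optional[str]:
        for sid, seg in self.segments.items():
            if seg.chain == chain and seg.first <= seq_id <= seg.last:
                return sid
        return None


def load_segment_config(path: str | os.PathLike) -> SegmentConfig:
    """Load a YAML segment config.

    Schema::

        segments:
          P1: {chain: A, first: 2, last: 35, cc_name: P1, heptad_start: a}
          ...
        dimers:
          - [P1, P2, parallel]
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping) or "segments" not in raw:
        raise StructureError(f"{path}: expected a mapping with a 'segments' block")
    segments = {}
    for sid, d in raw["segments"].items():
        segments[sid] = Segment(
            segment_id=sid, chain=str(d.get("chain", "A")),
            first=int(d["first"]), last=int(d["last"]),
            cc_name=str(d.get("cc_name", sid)),
            heptad_start=str(d.get("heptad_start", "a")),
        )
    dimers = [tuple(x) for x in raw.get("dimers", [])]
    return SegmentConfig(segments=segments, dimers=dimers)
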