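"""SASA, lattice neighbors, interfaces, Matthews coefficient."""

import numpy as np
import pytest

from ccorigami.packing import (MATTHEWS_CONST, lattice_neighbors,
                               packing_summary, sasa, unique_interfaces,
                               contact_position_profile)
from ccorigami.structures import (Atom, Residue, Segment, SegmentConfig,
                                  Structure, StructureError, UnitCell)


def _one_atom(element="C"):
    return Structure(chains={"A": [Residue(1, "GLY",
                                           [Atom("CA", element, [0, 0, 0])])]})


def test_sasa_single_atom_closed_form():
    areas = sasa(_one_atom())
    assert areas.sum() == pytest.approx(4 * np.pi * (1.7 + 1.4) ** 2, rel=1e-12)


def test_sasa_distant_atoms_are_fully_exposed():
    coords = np.array([[0.0, 0, 0], [10.0, 0, 0]])
    radii = np.array([1.6, 1.6])
    areas = sasa((coords, radii))
    iso = 4 * np.pi * 3.0**2
    np.testing.assert_allclose(areas, iso, rtol=1e-12)


def test_sasa_self_convergence():
    rng = np.random.default_rng(0)
    coords = rng.normal(0, 4, (50, 3))
    radii = np.full(50, 1.7)
    coarse = sasa((coords, radii), n_sphere_points=960).sum()
    fine = sasa((coords, radii), n_sphere_points=4000).sum()
    assert abs(coarse - fine) / fine < 0.02


def test_sasa_unknown_element_raises():
    with pytest.raises(StructureError, match="XX"):
        sasa(_one_atom(element="XX"))


def _touching_sphere_crystal(scale=1.0):
    st = _one_atom()
    a = (2 * 1.7 + 1.0) * scale  # overlapping solvent shells when scale=1
    st.cell = UnitCell(a, a, a, 90, 90, 90, "P 1")
    return st


def test_cubic_sphere_packing_has_six_neighbors_three_interfaces():
    st = _touching_sphere_crystal()
    nb = lattice_neighbors(st, st.cell)
    assert len(nb) == 6
    assert {n.translation for n in nb} == {
        (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)}
    clusters = unique_interfaces(nb)
    assert len(clusters) == 3
    for c in clusters:
        assert tuple(-x for x in c.representative) in c.members


def test_sparse_cell_has_no_neighbors():
    st = _touching_sphere_crystal(scale=7.0)
    assert lattice_neighbors(st, st.cell) == []
    assert unique_interfaces([]) == []


def test_neighbor_list_closed_under_negation(triangle_model):
    st = triangle_model.structure
    cell = UnitCell(60, 60, 40, 90, 90, 90, "P 1")
    nb = lattice_neighbors(st, cell, n_sphere_points=240)
    trans = {n.translation for n in nb}
    assert trans, "dense synthetic cell should make contacts"
    assert trans == {tuple(-x for x in t) for t in trans}


def test_non_p1_rejected(triangle_model):
    cell = UnitCell(60, 60, 40, 90, 90, 90, "P 21 21 21")
    with pytest.raises(StructureError, match="P1"):
        lattice_neighbors(triangle_model.structure, cell)


def test_matthews_closed_form():
    st = _touching_sphere_crystal()
    mass = st.cell.volume / (2 * MATTHEWS_CONST)  # makes Vm = 2·1.23 = 2.46
    ps = packing_summary(st, st.cell, mass=mass, neighbors=[])
    assert ps.matthews_vm == pytest.approx(2.46)
    assert ps.solvent_fraction == pytest.approx(0.500)
    assert ps.buried_fraction == 0.0
    assert ps.n_neighbors == 0


def test_solvent_fraction_monotone_in_vm():
    st = _touching_sphere_crystal()
    fractions = [packing_summary(st, st.cell, mass=st.cell.volume / vm,
                                 neighbors=[]).solvent_fraction
                 for vm in (1.8, 2.2, 2.6, 3.0)]
    assert all(b > a for a, b in zip(fractions, fractions[1:]))


def test_buried_area_symmetric_between_partners():
    # two atoms at touching distance: each loses the same area
    coords = np.array([[0.0, 0, 0], [3.0, 0, 0]])
    radii = np.array([1.7, 1.7])
    iso = sasa((coords[:1], radii[:1]), n_sphere_points=4000).sum()
    pair = sasa((coords, radii), n_sphere_points=4000)
    loss_a = iso - pair[0]
    loss_b = iso - pair[1]
    assert loss_a == pytest.approx(loss_b, rel=0.01)
    assert loss_a > 0


def test_packing_translation_invariance():
    st = _touching_sphere_crystal()
    mass = 30.0
    base = packing_summary(st, st.cell, mass=mass)
    shifted = st.translated(np.array(st.cell.vectors()[0]) + [0.1, 0.2, 0.3])
    shifted.cell = st.cell
    moved = packing_summary(shifted, st.cell, mass=mass)
    assert moved.n_neighbors == base.n_neighbors
    assert moved.total_buried == pytest.approx(base.total_buried, rel=1e-6)


def _two_helix_crystal():
    """Vertical helical columns with Ser donors facing ±x crystal contacts."""
    residues = []
    for i in range(8):
        z = 1.5 * i
        atoms = [Atom("N", "N", [0, 0, z - 0.5]), Atom("CA", "C", [0, 0, z]),
                 Atom("C", "C", [0, 0.5, z + 0.5]), Atom("O", "O", [0, 1.2, z + 0.7]),
                 Atom("CB", "C", [1.2, 0, z]),
                 Atom("OG", "O", [2.4, 0, z])]
        residues.append(Residue(i + 1, "SER", atoms))
    st = Structure(chains={"A": residues})
    # a-axis places the next column's amide 3.0 Å from the Ser OG
    st.cell = UnitCell(5.4, 30.0, 30.0, 90, 90, 90, "P 1")
    return st


def test_contact_position_profile_counts_engineered_class():
    st = _two_helix_crystal()
    # register chosen so the OG-bearing +x face is heptad position b
    cfg = SegmentConfig(
        segments={"H": Segment("H", "A", 1, 8, "helix", heptad_start="b")},
        dimers=[("H", "H", "parallel")])
    nb = lattice_neighbors(st, st.cell, n_sphere_points=240)
    registers = {"H": {i: "bcfbcfbc"[(i - 1) % 3] for i in range(1, 9)}}
    profile = contact_position_profile(st, nb, cfg, registers=registers)
    assert profile["b/c/f"] > 0
    assert profile["a/d"] == 0 and profile["e/g"] == 0


def test_empty_profile_without_neighbors():
    st = _two_helix_crystal()
    cfg = SegmentConfig(
        segments={"H": Segment("H", "A", 1, 8, "helix")},
        dimers=[("H", "H", "parallel")])
    profile = contact_position_profile(st, [], cfg)
    assert profile == {"b/c/f": 0, "e/g": 0, "a/d": 0}
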