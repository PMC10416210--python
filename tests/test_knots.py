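"""Knot invariants: KMT reduction, closures, Alexander determinants."""

import numpy as np
import pytest

from ccorigami.knots import (alexander_det, classify_knot, close_chain,
                             kmt_reduce, knot_core, make_parametric_knot)

# |Δ(−1)| of the standard diagrams, frozen from hand-built Alexander
# matrices: trefoil minor [[1,1],[-2,1]] -> 3; figure-eight 3x3 minor -> 5.
FIXTURES = [("unknot", 60, 1), ("trefoil", 60, 3), ("figure8", 80, 5)]


@pytest.mark.parametrize("kind,npts,det", FIXTURES)
def test_alexander_determinant_of_fixture_curves(kind, npts, det):
    curve = make_parametric_knot(kind, npts)
    assert alexander_det(curve) == det


@pytest.mark.parametrize("kind,npts,det", FIXTURES)
def test_kmt_preserves_determinant(kind, npts, det):
    curve = make_parametric_knot(kind, npts)
    reduced = kmt_reduce(curve)
    assert len(reduced) <= len(curve)
    assert alexander_det(reduced) == det
    # idempotence at the fixed point
    again = kmt_reduce(reduced)
    assert len(again) == len(reduced)


def test_kmt_collapses_planar_polygons():
    assert len(kmt_reduce(make_parametric_knot("unknot", 100))) <= 4
    assert len(kmt_reduce(make_parametric_knot("unknot", 1000))) <= 4


@pytest.mark.parametrize("kind,npts,det", FIXTURES)
def test_determinant_invariant_under_projection(kind, npts, det):
    curve = make_parametric_knot(kind, npts)
    rng = np.random.default_rng(7)
    for _ in range(10):
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])
        assert alexander_det(curve @ rot.T) == det


@pytest.mark.parametrize("kind,npts,det", FIXTURES)
def test_determinant_mirror_invariant(kind, npts, det):
    curve = make_parametric_knot(kind, npts)
    assert alexander_det(curve * np.array([1.0, 1.0, -1.0])) == det


def test_parametric_knot_validation():
    with pytest.raises(ValueError):
        make_parametric_knot("trefoil", 20)
    with pytest.raises(ValueError):
        make_parametric_knot("granny", 60)


def test_straight_line_closes_to_unknot():
    line = np.column_stack([np.linspace(0, 30, 12), np.zeros(12), np.zeros(12)])
    closed = close_chain(line, method="radial")
    assert alexander_det(kmt_reduce(closed)) == 1


def test_radial_closure_matches_direct_for_nearly_closed_loop():
    curve = make_parametric_knot("trefoil", 120)  # termini one step apart
    direct = alexander_det(kmt_reduce(np.vstack([curve, curve[:1]])))
    radial = alexander_det(kmt_reduce(close_chain(curve, method="radial")))
    assert direct == radial == 3


def test_random_closure_votes_on_open_trefoil():
    curve = make_parametric_knot("trefoil", 120)
    closures = close_chain(curve, method="random_sphere", n_votes=100, seed=0)
    dets = [alexander_det(kmt_reduce(c)) for c in closures]
    assert sum(d == 3 for d in dets) >= 90


def test_classify_open_trefoil():
    curve = make_parametric_knot("trefoil", 120)[3:]
    res = classify_knot(curve)
    assert res.knot_call == "3_1" and res.determinant == 3
    assert res.core is not None and res.depth is not None
    lo, hi = res.core
    assert 0 <= lo < hi <= len(curve) - 1


def test_classify_figure_eight_call():
    curve = make_parametric_knot("figure8", 100)[2:]
    res = classify_knot(curve, find_core=False)
    assert res.knot_call == "4_1" and res.determinant == 5


def test_knot_core_of_unknot_is_empty():
    line = np.column_stack([np.linspace(0, 50, 20),
                            np.sin(np.linspace(0, 3, 20)), np.zeros(20)])
    core, depth, mat = knot_core(line)
    assert core is None and depth is None and mat is None


def test_triangle_model_is_trefoil(triangle_model):
    res = classify_knot(triangle_model.structure, "A")
    assert res.knot_call == "3_1"
    n = len(triangle_model.structure.chains["A"])
    assert res.depth is not None and res.depth < 0.25 * n  # shallow knot
    lo, hi = res.core
    # both triangle passes are needed: the core spans most of the chain
    assert hi - lo > 0.5 * n


def test_planar_control_is_unknot(planar_model):
    res = classify_knot(planar_model.structure, "A", find_core=False)
    assert res.knot_call == "0_1"


def test_knot_calls_stable_under_parameter_jitter():
    from ccorigami.builder import build_origami, default_topology
    from ccorigami.crick import CrickParams
    rng = np.random.default_rng(3)
    for _ in range(2):
        f = lambda: 1 + rng.uniform(-0.1, 0.1)
        p = CrickParams(r0=4.9 * f(), w0=-3.6 * f(), r1=2.26 * f(),
                        rise=1.51 * f())
        params = {k: p for k in ("P1", "P2", "P3", "P4", "GCN")}
        knotted = build_origami(default_topology(), dimer_params=params)
        control = build_origami(default_topology(plane_crossing=False),
                                dimer_params=params)
        assert classify_knot(knotted.structure, "A",
                             find_core=False).knot_call == "3_1"
        assert classify_knot(control.structure, "A",
                             find_core=False).knot_call == "0_1"
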