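"""Crick model generation, fitting and superposition."""

import numpy as np
import pytest

from ccorigami.crick import (CANONICAL_DIMER, CrickParams, build_dimer,
                             build_helix, fit_crick, superpose)


def test_degenerate_superhelix_is_straight_helix():
    p = CrickParams(r0=0.0, w0=0.0, r1=2.26, w1=102.857, phi0=0, phi1=0, rise=1.51)
    pts = build_helix(p, 8)
    radial = np.hypot(pts[:, 0], pts[:, 1])
    np.testing.assert_allclose(radial, 2.26, atol=1e-9)
    assert pts[-1, 2] - pts[0, 2] == pytest.approx(7 * 1.51)


def test_two_residue_chord_matches_closed_form():
    p = CANONICAL_DIMER
    pts = build_helix(p, 2)
    assert len(pts) == 2
    chord = np.linalg.norm(pts[1] - pts[0])
    # closed form from the parameterization at i=0,1
    direct = np.linalg.norm(build_helix(p, 3)[1] - build_helix(p, 3)[0])
    assert chord == pytest.approx(direct, abs=1e-12)
    # α-helical parameters give the canonical ~3.8 Å spacing
    assert chord == pytest.approx(3.8, abs=0.15)


def test_parallel_dimer_geometry():
    a, b = build_dimer(CANONICAL_DIMER, 28)
    # inter-axis separation: windowed centroids sit on each helix axis
    ax_a = np.array([a[i:i + 7].mean(axis=0) for i in range(22)])
    ax_b = np.array([b[i:i + 7].mean(axis=0) for i in range(22)])
    sep = np.linalg.norm((ax_a - ax_b)[:, :2], axis=1)
    # windowed centroids track each helix axis to within the small inward
    # bias of averaging over a curved arc
    np.testing.assert_allclose(sep, 2 * CANONICAL_DIMER.r0, atol=0.3)
    prog_a = a[-1] - a[0]
    prog_b = b[-1] - b[0]
    assert prog_a @ prog_b > 0


def test_antiparallel_dimer_reverses_progression():
    a, b = build_dimer(CANONICAL_DIMER, 28, orientation="antiparallel")
    assert (a[-1] - a[0]) @ (b[-1] - b[0]) < 0


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        CrickParams(r0=-1.0)
    with pytest.raises(ValueError):
        CrickParams(r1=0.0)
    with pytest.raises(ValueError):
        build_helix(CANONICAL_DIMER, 1)


@pytest.mark.parametrize("r0", [0.0, 2.0, 4.9, 8.0])
def test_fit_recovers_built_parameters(r0):
    p = CrickParams(r0=r0, w0=-3.6 if r0 else 0.0, r1=2.26, w1=102.857,
                    phi0=30.0, phi1=140.0, rise=1.51)
    chains = build_dimer(p, 28)
    fit = fit_crick(chains)
    assert fit.rmsd_fit < 1e-6
    for name in ("r1", "rise"):
        got, want = getattr(fit.params, name), getattr(p, name)
        assert got == pytest.approx(want, abs=max(1e-3, 1e-3 * abs(want))), name
    if r0 > 0.5:
        assert fit.params.r0 == pytest.approx(r0, abs=1e-3)
        assert fit.params.w0 == pytest.approx(p.w0, abs=1e-3)
        assert fit.params.w1 == pytest.approx(p.w1, abs=1e-3)
        # minor phase is gauge-free (unlike phi0, which absorbs the frame)
        assert fit.params.phi1 % 360 == pytest.approx(140.0, abs=0.1)
    else:
        # degenerate superhelix: only the combined angular advance per
        # residue is identifiable (w0 and w1 trade off at r0 = 0)
        assert fit.params.r0 < 0.05
        assert (fit.params.w0 + fit.params.w1) % 360 == pytest.approx(
            102.857, abs=0.01)


def test_fit_straight_pair_reports_near_zero_radius():
    p = CrickParams(r0=0.0, w0=0.0, phi1=0.0)
    chains = build_dimer(p, 21)
    fit = fit_crick(chains)
    assert fit.params.r0 < 0.05


def test_fit_noisy_recovery_within_five_percent():
    p = CANONICAL_DIMER
    a, b = build_dimer(p, 28)
    rng = np.random.default_rng(0)
    fit = fit_crick([a + rng.normal(0, 0.3, a.shape),
                     b + rng.normal(0, 0.3, b.shape)])
    for name in ("r0", "w0", "r1", "w1", "rise"):
        got, want = getattr(fit.params, name), getattr(p, name)
        assert abs(got - want) / abs(want) < 0.05, name
    # rmsd of the fit tracks the applied 3-D noise scale (σ√3, minus the
    # d.o.f. absorbed by the model)
    assert 0.3 < fit.rmsd_fit < 0.55


def test_fit_objective_not_worse_than_truth():
    p = CANONICAL_DIMER
    a, b = build_dimer(p, 28)
    rng = np.random.default_rng(1)
    na, nb = a + rng.normal(0, 0.2, a.shape), b + rng.normal(0, 0.2, b.shape)
    fit = fit_crick([na, nb])
    truth_resid = np.sqrt(np.mean(np.sum(
        (np.vstack([na, nb]) - np.vstack([a, b])) ** 2, axis=1)))
    assert fit.rmsd_fit <= truth_resid + 1e-9


def _random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def test_superpose_identity_and_rigid_invariance():
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(25, 3)) * 10
    _, _, rmsd0 = superpose(pts, pts)
    assert rmsd0 == pytest.approx(0.0, abs=1e-12)
    for _ in range(5):
        rot = _random_rotation(rng)
        moved = pts @ rot.T + rng.normal(size=3) * 50
        _, _, rmsd = superpose(pts, moved)
        assert rmsd < 1e-9


def _quaternion_oracle_rmsd(a, b):
    """Horn's closed-form quaternion superposition (independent route)."""
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    m = bc.T @ ac
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    e0 = (ac**2).sum() + (bc**2).sum()
    return float(np.sqrt(max(e0 - 2 * lam, 0.0) / len(a)))


def test_superpose_matches_quaternion_oracle_on_jittered_dimer():
    a, _ = build_dimer(CANONICAL_DIMER, 28)
    rng = np.random.default_rng(0)
    b = a + rng.normal(0, 0.5, a.shape)
    rot = _random_rotation(rng)
    b = b @ rot.T + [3.0, -2.0, 7.0]
    _, _, rmsd = superpose(a, b)
    assert rmsd == pytest.approx(_quaternion_oracle_rmsd(a, b), abs=1e-9)
    assert rmsd == pytest.approx(0.5 * np.sqrt(3), rel=0.2)
    # symmetry of rmsd in its arguments
    _, _, back = superpose(b, a)
    assert back == pytest.approx(rmsd, abs=1e-9)


def test_superpose_length_mismatch():
    with pytest.raises(ValueError):
        superpose(np.zeros((4, 3)), np.zeros((5, 3)))
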