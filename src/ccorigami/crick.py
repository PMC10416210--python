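"""Crick parametric coiled-coil model: generation, fitting, superposition.

The ideal coiled coil is described by a minor α-helix of radius ``r1``
(frequency ``w1`` deg/residue) wound around a superhelical axis of radius
``r0`` (frequency ``w0`` deg/residue) with axial rise per residue ``rise``.
Angles are degrees throughout the public surface.  A canonical left-handed
dimer has r0 ≈ 4.9 Å, w0 ≈ −3.6°/res, r1 ≈ 2.26 Å, w1 ≈ 102.857°/res,
rise ≈ 1.51 Å.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = ["CrickParams", "CrickFitResult", "CANONICAL_DIMER",
           "build_helix", "build_dimer", "fit_crick", "superpose"]

# minor-helix phase (deg) of heptad position 'a' in the convention where
# phase 0 points radially outward from the superhelical axis: positions a
# and d straddle the inward direction (180°) at ±(360/14)°.
PHASE_OF_A = 180.0 + 360.0 / 14.0
HEPTAD = "abcdefg"


@dataclass
class CrickParams:
    r0: float = 4.9          # superhelical radius, Å
    w0: float = -3.6         # superhelical frequency, deg/residue (−: left-handed)
    r1: float = 2.26         # minor helix radius, Å
    w1: float = 102.857      # minor helix frequency, deg/residue
    phi0: float = 0.0        # superhelical phase, deg
    phi1: float = PHASE_OF_A  # minor-helix phase of residue 0, deg
    rise: float = 1.51       # axial rise per residue along the superhelix axis, Å

    def __post_init__(self) -> None:
        vals = [self.r0, self.w0, self.r1, self.w1, self.phi0, self.phi1, self.rise]
        if not all(np.isfinite(vals)):
            raise ValueError("Crick parameters must be finite")
        if self.r0 < 0 or self.r1 <= 0 or self.rise <= 0:
            raise ValueError("require r0 >= 0, r1 > 0, rise > 0")

    @property
    def pitch(self) -> float:
        """Superhelical pitch, Å (infinite for a straight helix)."""
        if self.w0 == 0:
            return np.inf
        return self.rise * 360.0 / abs(self.w0)

    @property
    def pitch_angle(self) -> float:
        """Signed angle (deg) between a helix axis and the superhelical axis."""
        return np.degrees(np.arctan2(self.r0 * np.radians(self.w0), self.rise))


CANONICAL_DIMER = CrickParams()


def _canonical_points(p: CrickParams, n_res: int) -> np.ndarray:
    i = np.arange(n_res)
    a = np.radians(p.phi0 + p.w0 * i)
    b = np.radians(p.phi1 + p.w1 * i)
    alpha = np.arctan2(p.r0 * np.radians(p.w0), p.rise)
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    x = p.r0 * ca + p.r1 * (ca * cb - np.cos(alpha) * sa * sb)
    y = p.r0 * sa + p.r1 * (sa * cb + np.cos(alpha) * ca * sb)
    z = p.rise * i - p.r1 * np.sin(alpha) * sb
    return np.column_stack([x, y, z])


def build_helix(params: CrickParams, n_res: int,
                axis_frame: Optional[tuple[np.ndarray, np.ndarray]] = None) -> np.ndarray:
    """Cα positions of one helix of an ideal coiled coil.

    ``axis_frame`` is ``(origin, triad)`` with triad columns = local x, y, z
    axes; the superhelical axis runs along local z through the origin.
    """
    if n_res < 2:
        raise ValueError("need n_res >= 2")
    pts = _canonical_points(params, n_res)
    if axis_frame is not None:
        origin, triad = axis_frame
        origin = np.asarray(origin, dtype=float)
        triad = np.asarray(triad, dtype=float)
        pts = pts @ triad.T + origin
    return pts


def build_dimer(params: CrickParams, n_res: int,
                orientation: str = "parallel") -> tuple[np.ndarray, np.ndarray]:
    """Two helices of a CC dimer related by a 180° rotation about the axis."""
    chain_a = build_helix(params, n_res)
    chain_b = build_helix(replace(params, phi0=params.phi0 + 180.0), n_res)
    if orientation == "parallel":
        return chain_a, chain_b
    if orientation == "antiparallel":
        # flip chain B end-over-end about the x axis, then restore axial span
        flipped = chain_b * np.array([1.0, -1.0, -1.0])
        flipped[:, 2] += chain_b[-1, 2] + chain_b[0, 2]
        return chain_a, flipped
    raise ValueError(f"unknown orientation {orientation!r}")


# ---------------------------------------------------------------------------
# fitting


@dataclass
class CrickFitResult:
    params: CrickParams
    rmsd_fit: float
    n_res: int
    phi1_b: Optional[float] = None  # minor phase of the second chain, if fitted


def _rotation(v: np.ndarray) -> np.ndarray:
    """Rotation matrix from a rotation vector (Rodrigues)."""
    theta = np.linalg.norm(v)
    if theta < 1e-12:
        return np.eye(3)
    k = v / theta
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)


def _axis_frame_estimate(chains: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Estimate the superhelix axis frame from windowed centroids of the chains."""
    n = min(len(c) for c in chains)
    pooled = np.mean([np.asarray(c)[:n] for c in chains], axis=0)
    w = min(7, n - 1)
    axis_pts = np.array([pooled[i:i + w].mean(axis=0) for i in range(n - w + 1)])
    center = axis_pts.mean(axis=0)
    if len(axis_pts) < 2:
        direction = np.array([0.0, 0.0, 1.0])
    else:
        _, _, vt = np.linalg.svd(axis_pts - center)
        direction = vt[0]
        if direction @ (axis_pts[-1] - axis_pts[0]) < 0:
            direction = -direction
    # complete a right-handed triad
    ref = np.array([1.0, 0.0, 0.0])
    if abs(direction @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    x = ref - (ref @ direction) * direction
    x /= np.linalg.norm(x)
    y = np.cross(direction, x)
    triad = np.column_stack([x, y, direction])
    return center, triad


def fit_crick(ca_pair: Sequence[np.ndarray] | np.ndarray,
              orientation: str = "parallel") -> CrickFitResult:
    """Least-squares Crick fit of one helix or a dimer of Cα chains.

    A shared superhelical axis is fitted together with the model parameters;
    the second chain of a dimer shares all parameters except its minor-helix
    phase and sits at superhelical phase phi0 + 180°.  Multi-start over the
    phases keeps the fit away from local minima.
    """
    if isinstance(ca_pair, np.ndarray) and ca_pair.ndim == 2:
        chains = [np.asarray(ca_pair, dtype=float)]
    else:
        chains = [np.asarray(c, dtype=float) for c in ca_pair]
    if not 1 <= len(chains) <= 2:
        raise ValueError("fit_crick takes one or two Cα chains")
    for c in chains:
        if len(c) < 14:
            raise ValueError("need at least two full heptads (14 residues) per chain")
    if orientation == "antiparallel" and len(chains) == 2:
        chains = [chains[0], chains[1][::-1]]

    n = min(len(c) for c in chains)
    chains = [c[:n] for c in chains]
    obs = np.concatenate(chains)
    center, triad = _axis_frame_estimate(chains)
    # observed coordinates in the estimated axis frame
    local = [(c - center) @ triad for c in chains]
    obs_local = np.concatenate(local)
    two = len(chains) == 2

    # initial scalar estimates from the windowed geometry
    rise0 = max((local[0][-1, 2] - local[0][0, 2]) / (n - 1), 0.5)
    w = min(7, n - 1)
    ax0 = np.array([local[0][i:i + w].mean(axis=0) for i in range(n - w + 1)])
    r0_init = float(np.hypot(ax0[:, 0], ax0[:, 1]).mean())
    ang = np.unwrap(np.arctan2(ax0[:, 1], ax0[:, 0]))
    w0_init = np.degrees((ang[-1] - ang[0]) / max(len(ax0) - 1, 1)) if r0_init > 0.5 else -3.6
    phi0_init = np.degrees(ang[0]) - w0_init * (w - 1) / 2.0 if r0_init > 0.5 else 0.0

    def residuals(x: np.ndarray) -> np.ndarray:
        r0, w0, r1, w1, rise, phi0, phi1a = x[:7]
        phi1b = x[7] if two else 0.0
        rot = _rotation(x[-6:-3])
        trans = x[-3:]
        try:
            p = CrickParams(abs(r0), w0, abs(r1), w1, phi0, phi1a, abs(rise))
        except ValueError:
            return np.full(obs_local.size, 1e3)
        model = [_canonical_points(p, n)]
        if two:
            pb = replace(p, phi0=phi0 + 180.0, phi1=phi1b)
            model.append(_canonical_points(pb, n))
        m = np.concatenate(model)
        return ((m @ rot.T + trans) - obs_local).ravel()

    best = None
    phase_grid = [0.0, 90.0, 180.0, 270.0]
    for phi1a0, phi1b0 in itertools.product(phase_grid, phase_grid if two else [0.0]):
        x0 = [r0_init, w0_init, 2.26, 102.857, rise0, phi0_init, phi1a0]
        if two:
            x0.append(phi1b0)
        x0 += [0.0] * 6
        sol = least_squares(residuals, x0, method="lm", max_nfev=4000)
        if best is None or sol.cost < best.cost:
            best = sol
        if np.sqrt(2 * best.cost / obs.size * 3) < 1e-8:
            break
    assert best is not None
    rmsd = float(np.sqrt(np.mean(np.sum(
        best.fun.reshape(-1, 3) ** 2, axis=1))))
    if rmsd > 5.0:
        raise RuntimeError(f"Crick fit failed to converge (best residual {rmsd:.2f} Å)")
    x = best.x
    params = CrickParams(abs(x[0]), x[1], abs(x[2]), x[3],
                         x[5] % 360.0, x[6] % 360.0, abs(x[4]))
    return CrickFitResult(params=params, rmsd_fit=rmsd, n_res=n,
                          phi1_b=(x[7] % 360.0) if two else None)


def superpose(ca1: np.ndarray, ca2: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ca2 onto ca1 (Kabsch).

    Returns ``(rotation, translation, rmsd)`` with ``ca2 @ R.T + t ≈ ca1``.
    """
    a = np.asarray(ca1, dtype=float)
    b = np.asarray(ca2, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if len(a) < 3:
        raise ValueError("need at least 3 points")
    ca_c, cb_c = a.mean(axis=0), b.mean(axis=0)
    h = (b - cb_c).T @ (a - ca_c)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ca_c - rot @ cb_c
    moved = b @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - a) ** 2, axis=1))))
    return rot, trans, rmsd
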