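"""Debye-formula SAXS profiles and χ² scoring against experiment.

The orientationally averaged intensity of a point-scatterer model is
I(q) = Σᵢ Σⱼ fᵢ fⱼ sin(q rᵢⱼ)/(q rᵢⱼ).  Models are coarse-grained to one
scatterer per residue (Cα position, weight = residue electron count); no
hydration shell or excluded-volume correction is applied, so absolute
agreement with measured curves is limited by that approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import pdist

from .structures import Structure, StructureError, ca_trace

__all__ = ["SaxsCurve", "SaxsFitResult", "debye_profile", "guinier_rg",
           "chi2_fit", "residue_weights", "read_saxs_curve", "radius_of_gyration"]

# electron counts of protein residues (neutral side chains)
RESIDUE_ELECTRONS = {
    "GLY": 30, "ALA": 38, "SER": 46, "PRO": 52, "VAL": 54, "THR": 54,
    "CYS": 54, "LEU": 62, "ILE": 62, "ASN": 60, "ASP": 59, "GLN": 68,
    "LYS": 71, "GLU": 67, "MET": 70, "HIS": 72, "PHE": 78, "ARG": 85,
    "TYR": 86, "TRP": 98,
}


@dataclass
class SaxsCurve:
    q: np.ndarray
    intensity: np.ndarray
    sigma: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.q < 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be non-negative and strictly increasing")


@dataclass
class SaxsFitResult:
    scale: float
    chi2: float
    n_points: int


def residue_weights(structure: Structure, chain: str) -> tuple[np.ndarray, np.ndarray]:
    """Cα coordinates and per-residue electron-count weights for one chain."""
    coords, weights = [], []
    for r in structure.chains[chain]:
        at = r.ca
        if at is None:
            continue
        coords.append(at.coord)
        weights.append(RESIDUE_ELECTRONS.get(r.name, 62))
    return np.array(coords, dtype=float), np.array(weights, dtype=float)


def debye_profile(coords: np.ndarray, weights: np.ndarray,
                  q: np.ndarray) -> SaxsCurve:
    """Debye-sum scattering profile of weighted point scatterers."""
    coords = np.asarray(coords, dtype=float)
    weights = np.asarray(weights, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("negative q")
    if len(coords) == 0:
        raise ValueError("need at least one scatterer")
    intensity = np.full(len(q), float(np.sum(weights**2)))
    if len(coords) > 1:
        rij = pdist(coords)
        iu = np.triu_indices(len(coords), k=1)
        wij = weights[iu[0]] * weights[iu[1]]
        # block over q to bound the (n_q × n_pairs) working set
        block = max(1, int(2e7 // max(len(rij), 1)))
        for lo in range(0, len(q), block):
            qr = np.outer(q[lo:lo + block], rij)
            sinc = np.ones_like(qr)
            nz = qr > 1e-12
            sinc[nz] = np.sin(qr[nz]) / qr[nz]
            intensity[lo:lo + block] += 2.0 * (sinc @ wij)
    return SaxsCurve(q=q, intensity=intensity)


def radius_of_gyration(coords: np.ndarray,
                       weights: Optional[np.ndarray] = None) -> float:
    coords = np.asarray(coords, dtype=float)
    w = np.ones(len(coords)) if weights is None else np.asarray(weights, float)
    center = np.average(coords, axis=0, weights=w)
    return float(np.sqrt(np.average(np.sum((coords - center) ** 2, axis=1),
                                    weights=w)))


def guinier_rg(curve: SaxsCurve, qrg_max: float = 1.3) -> float:
    """Radius of gyration from the Guinier region (ln I vs q² slope).

    The window is found iteratively: fit, estimate Rg, drop points with
    q·Rg > the limit, refit until stable.
    """
    q = curve.q
    mask = (q > 0) & (curve.intensity > 0)
    if mask.sum() < 3:
        raise ValueError("not enough positive-intensity points")
    rg = 0.0
    for _ in range(30):
        use = mask if rg == 0 else mask & (q * rg <= qrg_max)
        if use.sum() < 3:
            use = mask & (q <= np.sort(q[mask])[2])
        slope, _ = np.polyfit(q[use] ** 2, np.log(curve.intensity[use]), 1)
        new_rg = float(np.sqrt(max(-3.0 * slope, 0.0)))
        if abs(new_rg - rg) < 1e-6:
            break
        rg = new_rg
    return rg


def chi2_fit(model: SaxsCurve, experiment: SaxsCurve) -> SaxsFitResult:
    """Reduced χ² of the model against experiment with a fitted scale.

    The model is linearly interpolated onto the experimental q grid
    (no extrapolation); the scale c = Σ(Iₘ·Iₑ/σ²)/Σ(Iₘ²/σ²) is the
    closed-form weighted least-squares minimizer.
    """
    q = experiment.q
    inside = (q >= model.q[0]) & (q <= model.q[-1])
    if inside.sum() < 2:
        raise ValueError("experimental grid does not overlap the model")
    qm = q[inside]
    im = np.interp(qm, model.q, model.intensity)
    ie = experiment.intensity[inside]
    if experiment.sigma is not None:
        sig = experiment.sigma[inside]
    else:
        import warnings
        warnings.warn("no experimental uncertainties: using unit weights")
        sig = np.ones_like(ie)
    w = 1.0 / sig**2
    scale = float(np.sum(w * im * ie) / np.sum(w * im * im))
    resid = (scale * im - ie) / sig
    n = len(qm)
    chi2 = float(np.sum(resid**2) / max(n - 1, 1))
    return SaxsFitResult(scale=scale, chi2=chi2, n_points=n)


def read_saxs_curve(path) -> SaxsCurve:
    """Read a 3-column (q, I, σ) or 2-column (q, I) text file."""
    data = np.loadtxt(path, comments=("#", ";"))
    if data.ndim != 2 or data.shape[1] < 2:
        raise StructureError(f"{path}: expected 2 or 3 numeric columns")
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    return SaxsCurve(q=data[:, 0], intensity=data[:, 1], sigma=sigma)
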