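"""Exterior multipole moments of point-charge configurations.

The Coulomb potential generated inside a ball of radius r_cut by the
charges *outside* it is a regular solid-harmonic series,

    V_i^>(r) = Σ_{lm} M_{i,lm}^> r^l Y_l^m(r̂),
    M_{i,lm}^> = 4π/(2l+1) Σ_{j: d_ij > r_cut} w_j Y_l^m(r̂_ij) / d_ij^{l+1},

(real orthonormal harmonics, shared package convention; the 4π/(2l+1)
prefactor follows from the Legendre addition theorem and is asserted by
the reconstruction tests rather than trusted). These moments are the
physical-interpretation oracle for the descriptor coefficients: with the
monomial basis and p = 1 the two agree entry by entry.

Brute-force and Coulomb-only by design — this module exists to serve as
an independent reference, not as a production evaluator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spherical import lm_index, n_lm, real_sph_harm
from .structures import Structure

__all__ = ["MultipoleSet", "exterior_multipoles", "reconstruct_exterior_field"]


@dataclass
class MultipoleSet:
    """Exterior moments of one center: flat (l, m) array plus bookkeeping."""

    moments: np.ndarray  # ((l_max+1)²,)
    r_cut: float
    l_max: int
    convention: str = "real-orthonormal/4pi-over-2l+1"

    def lm(self, l: int, m: int) -> float:
        return float(self.moments[lm_index(l, m)])


def exterior_multipoles(
    structure: Structure, center: int, r_cut: float, l_max: int
) -> MultipoleSet:
    """Moments M_{lm}^> of the atoms strictly outside the cutoff sphere.

    Aperiodic, Coulomb (p = 1) only. Atoms with d ≤ r_cut (including the
    center itself) are excluded; an exterior-empty configuration yields
    exactly zero moments.
    """
    if structure.is_periodic:
        raise ValueError("exterior multipoles are defined for aperiodic structures")
    if not 0 <= center < len(structure):
        raise IndexError(f"center index {center} out of range")
    rel = structure.positions - structure.positions[center]
    d = np.linalg.norm(rel, axis=1)
    ext = d > r_cut
    moments = np.zeros(n_lm(l_max))
    if np.any(ext):
        ylm = real_sph_harm(l_max, rel[ext])  # (n_ext, nlm)
        w = structure.weights[ext]
        for l in range(l_max + 1):
            sl = slice(lm_index(l, -l), lm_index(l, l) + 1)
            c_l = 4.0 * np.pi / (2.0 * l + 1.0)
            moments[sl] = c_l * (w / d[ext] ** (l + 1)) @ ylm[:, sl]
    return MultipoleSet(moments, float(r_cut), int(l_max))


def reconstruct_exterior_field(moments: MultipoleSet, r: np.ndarray) -> np.ndarray:
    """V^>(r) = Σ_lm M_lm r^l Y_lm(r̂) at points strictly inside the cutoff.

    Truncation error at radius |r| is bounded on the (|r|/d_min)^{l_max+1}
    scale, d_min the closest exterior source.
    """
    pts = np.atleast_2d(np.asarray(r, dtype=float))
    rad = np.linalg.norm(pts, axis=1)
    if np.any(rad >= moments.r_cut):
        raise ValueError("reconstruction is valid only inside the cutoff sphere")
    out = np.zeros(pts.shape[0])
    # the origin is regular: only the l=0 term survives there
    at0 = rad == 0.0
    out[at0] = moments.lm(0, 0) * real_sph_harm(0, np.array([[0, 0, 1.0]]))[0, 0]
    if np.any(~at0):
        ylm = real_sph_harm(moments.l_max, pts[~at0])
        acc = np.zeros(ylm.shape[0])
        for l in range(moments.l_max + 1):
            sl = slice(lm_index(l, -l), lm_index(l, l) + 1)
            acc += rad[~at0] ** l * (ylm[:, sl] @ moments.moments[sl])
        out[~at0] = acc
    return out if np.asarray(r).ndim == 2 else out[0]
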