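"""Smeared inverse-power-law kernels and total potential fields.

The atom density is a superposition of normalized Gaussians of width
``smearing`` (σ). Convolving 1/r^p with the density of a single atom
gives the smeared kernel

    g_p(r) = γ(p/2, r²/(2σ²)) / (Γ(p/2) · r^p),

with γ the lower incomplete gamma function, which is finite at the
origin for every p > 0 and approaches the bare 1/r^p from below. For
p = 1 it reduces to erf(r/(√2 σ))/r, the familiar smeared Coulomb
potential. Its 3-D Fourier transform has the closed form

    ĝ_p(k) = π^{3/2}/Γ(p/2) · (k²/4)^{(p-3)/2} · Γ((3-p)/2, k²σ²/2),

(upper incomplete gamma, extended to negative first argument by the
standard recurrence), which for p = 1 is 4π exp(-σ²k²/2)/k². Periodic
fields are evaluated by the reciprocal-space (Ewald-style) sum over
lattice vectors |k| ≤ k_cutoff; aperiodic fields by direct summation.

All potentials are in reduced units: the kernel is exactly 1/r^p at
large r. Physical prefactors (14.3996 eV·Å for electrostatics) belong
to the model/ground-truth layer, not here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import exp1, gamma, gammainc, gammaincc

from .structures import Structure, periodic_shifts

__all__ = [
    "InteractionSpec",
    "PotentialField",
    "smeared_kernel",
    "kernel_fourier",
    "kernel_fourier_k0",
    "reciprocal_vectors",
    "evaluate_field_periodic",
    "evaluate_field_direct",
]

DEFAULT_SMEARING = 1.0  # Å


@dataclass(frozen=True)
class InteractionSpec:
    """Exponent p of the 1/r^p interaction and Gaussian smearing σ (Å)."""

    p: float = 1.0
    smearing: float = DEFAULT_SMEARING

    def __post_init__(self) -> None:
        if not self.p > 0:
            raise ValueError("exponent p must be positive")
        if not self.smearing > 0:
            raise ValueError("smearing must be positive")

    @property
    def default_k_cutoff(self) -> float:
        """1.2 · 2π/σ — converges the reciprocal sum to well below 1%."""
        return 1.2 * 2.0 * np.pi / self.smearing


def smeared_kernel(spec: InteractionSpec, r) -> np.ndarray | float:
    """g_p(r); finite (limit value) at r = 0.

    The r→0 limit is 1 / ((2σ²)^{p/2} Γ(p/2 + 1)).
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0):
        raise ValueError("r must be non-negative")
    p, sig = spec.p, spec.smearing
    limit0 = 1.0 / ((2.0 * sig**2) ** (p / 2.0) * gamma(p / 2.0 + 1.0))
    # below ~1e-8 σ the series limit is exact to double precision and the
    # direct ratio would underflow to 0/0
    small = r_arr < 1e-8 * sig
    r_safe = np.where(small, sig, r_arr)
    with np.errstate(divide="ignore", invalid="ignore"):
        val = gammainc(p / 2.0, r_safe**2 / (2.0 * sig**2)) / r_safe**p
    out = np.where(small, limit0, val)
    return float(out) if np.isscalar(r) else out


def _upper_gamma(a: float, x: np.ndarray) -> np.ndarray:
    """Γ(a, x) for arbitrary real a and x > 0.

    scipy only covers a > 0; negative orders use
    Γ(a, x) = (Γ(a+1, x) - x^a e^{-x}) / a, recursing upward to a > 0,
    and Γ(0, x) = E₁(x).
    """
    if a > 0:
        return gamma(a) * gammaincc(a, x)
    if a == 0:
        return exp1(x)
    return (_upper_gamma(a + 1.0, x) - x**a * np.exp(-x)) / a


def kernel_fourier(spec: InteractionSpec, k) -> np.ndarray | float:
    """Radial Fourier transform ĝ_p(k) of the smeared kernel, k > 0."""
    k_arr = np.asarray(k, dtype=float)
    if np.any(k_arr <= 0):
        raise ValueError("k must be positive (the k=0 term is a policy choice)")
    p, sig = spec.p, spec.smearing
    a = (3.0 - p) / 2.0
    pref = np.pi**1.5 / gamma(p / 2.0)
    out = pref * (k_arr**2 / 4.0) ** ((p - 3.0) / 2.0) * _upper_gamma(
        a, k_arr**2 * sig**2 / 2.0
    )
    return float(out) if np.isscalar(k) else out


def kernel_fourier_k0(spec: InteractionSpec) -> float:
    """Finite k→0 limit of ĝ_p; exists only for p > 3."""
    p, sig = spec.p, spec.smearing
    if p <= 3:
        raise ValueError("the k=0 term diverges for p <= 3")
    return float(
        np.pi**1.5 / gamma(p / 2.0) * (2.0 * sig**2) ** ((3.0 - p) / 2.0)
        * 2.0 / (p - 3.0)
    )


def reciprocal_vectors(
    cell: np.ndarray, k_cutoff: float, half_space: bool = False
) -> np.ndarray:
    """Nonzero reciprocal-lattice vectors with |k| ≤ k_cutoff.

    The integer lattice is enumerated over a bounding box and filtered —
    simple, exact, adequate at desk scale. With ``half_space`` only one
    of each ±k pair is returned (lexicographically positive integer
    coordinates); sums over the full set equal twice the real part of
    the half-space sum for real densities.
    """
    b = 2.0 * np.pi * np.linalg.inv(cell).T  # rows are reciprocal vectors
    inv_b = np.linalg.inv(b)
    heights = 1.0 / np.linalg.norm(inv_b, axis=0)
    nmax = np.ceil(k_cutoff / heights).astype(int)
    rng = [np.arange(-n, n + 1) for n in nmax]
    grid = np.stack(np.meshgrid(*rng, indexing="ij"), axis=-1).reshape(-1, 3)
    if half_space:
        g0, g1, g2 = grid.T
        keep_half = (g0 > 0) | ((g0 == 0) & ((g1 > 0) | ((g1 == 0) & (g2 > 0))))
        grid = grid[keep_half]
    k = grid @ b
    norm = np.linalg.norm(k, axis=1)
    keep = (norm > 0) & (norm <= k_cutoff)
    return k[keep]


@dataclass
class PotentialField:
    """Evaluator for the total potential V(r) of a structure.

    Call :meth:`evaluate` with an (M, 3) array of Cartesian probe points.
    ``k_cutoff`` is set on the periodic (reciprocal-space) path only.
    """

    structure: Structure
    spec: InteractionSpec
    k_cutoff: float | None = None
    _kvecs: np.ndarray | None = None
    _coef: np.ndarray | None = None  # ĝ(|k|)·S(k)/Ω per k-vector
    _k0_term: float = 0.0
    _realspace_cutoff: float | None = None
    _weights: np.ndarray | None = None

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self._kvecs is not None:
            out = np.full(pts.shape[0], self._k0_term)
            # chunk the (n_points × n_k) phase matrix to bound memory
            chunk = max(1, int(8e6 // max(1, self._kvecs.shape[0])))
            for lo in range(0, pts.shape[0], chunk):
                phase = np.exp(1j * pts[lo : lo + chunk] @ self._kvecs.T)
                out[lo : lo + chunk] += (phase @ self._coef).real
            return out if points.ndim == 2 else out[0]
        # direct path
        st, w = self.structure, self._weights
        centers = [st.positions]
        if st.is_periodic:
            shifts = periodic_shifts(st.cell, self._realspace_cutoff)
            centers = [st.positions + s for s in shifts]
        out = np.zeros(pts.shape[0])
        for cen in centers:
            d = np.linalg.norm(pts[:, None, :] - cen[None, :, :], axis=-1)
            mask = d <= self._realspace_cutoff
            g = smeared_kernel(self.spec, d) * mask
            out += g @ w
        return out if points.ndim == 2 else out[0]

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return self.evaluate(points)


def evaluate_field_periodic(
    structure: Structure,
    spec: InteractionSpec,
    k_cutoff: float | None = None,
    weights: np.ndarray | None = None,
) -> PotentialField:
    """Reciprocal-space field V(r) = (1/Ω) Σ_{0<|k|≤kc} ĝ(|k|) S(k) e^{ik·r}.

    S(k) = Σ_j w_j e^{-ik·r_j}. The k = 0 term is omitted for p ≤ 3
    (neutralizing-background convention) and included via the finite
    limit of ĝ for p > 3. ``weights`` overrides the structure weights
    (used to build per-species fields).
    """
    if not structure.is_periodic:
        raise ValueError(
            "structure has no cell; use evaluate_field_direct for clusters"
        )
    if k_cutoff is None:
        k_cutoff = spec.default_k_cutoff
    if k_cutoff <= 0:
        raise ValueError("k_cutoff must be positive")
    w = structure.weights if weights is None else np.asarray(weights, float)
    kv = reciprocal_vectors(structure.cell, k_cutoff)
    gk = kernel_fourier(spec, np.linalg.norm(kv, axis=1))
    sk = np.exp(-1j * kv @ structure.positions.T) @ w
    vol = structure.volume
    k0 = 0.0
    if spec.p > 3:
        k0 = kernel_fourier_k0(spec) * float(np.sum(w)) / vol
    return PotentialField(
        structure, spec, k_cutoff, _kvecs=kv, _coef=gk * sk / vol, _k0_term=k0
    )


def evaluate_field_direct(
    structure: Structure,
    spec: InteractionSpec,
    realspace_cutoff: float = 30.0,
    weights: np.ndarray | None = None,
) -> PotentialField:
    """Real-space field V(r) = Σ_j w_j g_p(|r − r_j|) within a cutoff.

    For periodic structures the image sum converges absolutely only for
    p > 3; p ≤ 3 with a cell is refused (conditionally convergent —
    use the reciprocal-space path).
    """
    if structure.is_periodic and spec.p <= 3:
        raise ValueError(
            "direct lattice sum is conditionally convergent for p <= 3; "
            "use evaluate_field_periodic"
        )
    w = structure.weights if weights is None else np.asarray(weights, float)
    return PotentialField(
        structure, spec, None, _realspace_cutoff=realspace_cutoff, _weights=w
    )
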