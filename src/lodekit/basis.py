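"""Radial bases for the descriptor expansion.

Two families:

``monomial``
    One radial function per angular channel, R_{0l}(r) = (2l+3) r^l / r_c^{2l+3}.
    The plain r^l shape is what makes the descriptor coefficients equal the
    exterior multipole moments; the (2l+3)/r_c^{2l+3} normalization absorbs
    ∫_0^{r_c} r^{2l} · r² dr so that the identity holds with no extra factor
    under the plain d³r projection measure.

``gto``
    Gaussian-type radial functions r^l exp(-r²/(2 s_n²)), with widths s_n
    spanning [r_c/n_max, r_c] linearly, Löwdin-orthonormalized on [0, r_c]
    under the r² measure. The general-purpose basis (default n_max = 8).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import spherical_jn

__all__ = ["BasisSpec", "radial_projection"]

_N_QUAD = 160  # Gauss–Legendre order for radial integrals on [0, r_cut]


@dataclass
class BasisSpec:
    family: str = "gto"
    n_max: int = 8
    l_max: int = 3
    r_cut: float = 4.0
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.family not in ("monomial", "gto"):
            raise ValueError(f"unknown radial family {self.family!r}")
        if self.family == "monomial":
            self.n_max = 1
        if self.n_max < 1 or self.l_max < 0 or not self.r_cut > 0:
            raise ValueError("need n_max >= 1, l_max >= 0, r_cut > 0")

    # -- quadrature nodes shared by every radial integral ---------------
    def quad_nodes(self) -> tuple[np.ndarray, np.ndarray]:
        """GL nodes r_q and weights (including the r² measure) on [0, r_cut]."""
        if "quad" not in self._cache:
            x, w = np.polynomial.legendre.leggauss(_N_QUAD)
            r = 0.5 * self.r_cut * (x + 1.0)
            self._cache["quad"] = (r, 0.5 * self.r_cut * w * r**2)
        return self._cache["quad"]

    def _gto_coeffs(self, l: int) -> np.ndarray:
        """Löwdin coefficients C such that R_nl = Σ_m C[n,m] φ_ml."""
        key = ("gto", l)
        if key not in self._cache:
            r, w = self.quad_nodes()
            raw = self._gto_raw(l, r)  # (n, q)
            gram = (raw * w) @ raw.T
            evals, evecs = np.linalg.eigh(gram)
            if np.min(evals) <= 0:
                raise ValueError("GTO basis numerically degenerate; lower n_max")
            self._cache[key] = (evecs / np.sqrt(evals)) @ evecs.T
        return self._cache[key]

    def _gto_raw(self, l: int, r: np.ndarray) -> np.ndarray:
        widths = np.linspace(self.r_cut / self.n_max, self.r_cut, self.n_max)
        return r[None, :] ** l * np.exp(-(r[None, :] ** 2) / (2.0 * widths[:, None] ** 2))

    def evaluate(self, l: int, r: np.ndarray) -> np.ndarray:
        """R_nl(r) for n = 0..n_max-1; shape (n_max, len(r))."""
        if l > self.l_max:
            raise ValueError(f"l={l} exceeds l_max={self.l_max}")
        r = np.asarray(r, dtype=float)
        if self.family == "monomial":
            norm = (2.0 * l + 3.0) / self.r_cut ** (2 * l + 3)
            return (norm * r**l)[None, :]
        return self._gto_coeffs(l) @ self._gto_raw(l, r)

    def evaluate_stack(self, r: np.ndarray) -> list[np.ndarray]:
        """[R_nl(r) for l = 0..l_max], sharing the Gaussian factors.

        Equivalent to ``[evaluate(l, r) for l in ...]`` but ~l_max times
        cheaper for the GTO family, whose exponentials are l-independent.
        """
        r = np.asarray(r, dtype=float)
        if self.family == "monomial":
            return [self.evaluate(l, r) for l in range(self.l_max + 1)]
        widths = np.linspace(self.r_cut / self.n_max, self.r_cut, self.n_max)
        gauss = np.exp(-(r[None, :] ** 2) / (2.0 * widths[:, None] ** 2))
        out = []
        raw = gauss
        for l in range(self.l_max + 1):
            if l:
                raw = raw * r[None, :]
            out.append(self._gto_coeffs(l) @ raw)
        return out


def radial_projection(basis: BasisSpec, l: int, k) -> np.ndarray:
    """Spherical-Bessel transform I_nl(k) = ∫_0^{r_c} R_nl(r) j_l(kr) r² dr.

    Closed form for the monomial basis (∫ r^{l+2} j_l(kr) dr =
    r_c^{l+2} j_{l+1}(k r_c)/k); Gauss–Legendre quadrature for GTO.
    Returns shape (n_max, len(k)); scalar k gives (n_max,).
    """
    if l > basis.l_max:
        raise ValueError(f"l={l} exceeds l_max={basis.l_max}")
    k_arr = np.atleast_1d(np.asarray(k, dtype=float))
    if np.any(k_arr <= 0):
        raise ValueError("k must be positive")
    if basis.family == "monomial":
        rc = basis.r_cut
        norm = (2.0 * l + 3.0) / rc ** (2 * l + 3)
        out = (norm * rc ** (l + 2) * spherical_jn(l + 1, k_arr * rc) / k_arr)[None, :]
    else:
        r, w = basis.quad_nodes()  # w already carries the r² measure
        jl = spherical_jn(l, k_arr[:, None] * r[None, :])  # (nk, q)
        out = (basis.evaluate(l, r) * w) @ jl.T
    return out[:, 0] if np.isscalar(k) else out
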