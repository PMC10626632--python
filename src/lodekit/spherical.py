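"""Real spherical harmonics and spherical quadrature grids.

One convention is fixed here and used identically across the whole
package (descriptors, multipoles, short-range density): real harmonics,
orthonormal on the unit sphere, with no Condon–Shortley phase, so that

    Y_{1,-1} ∝ y,  Y_{1,0} ∝ z,  Y_{1,1} ∝ x   (positive prefactors).

Coefficients are stored flat over (l, m) with index l² + l + m.
"""

from __future__ import annotations

import numpy as np
from scipy.special import sph_harm_y

__all__ = ["lm_index", "n_lm", "real_sph_harm", "ball_grid", "sphere_grid"]


def lm_index(l: int, m: int) -> int:
    """Flat index of the (l, m) channel."""
    return l * l + l + m


def n_lm(l_max: int) -> int:
    return (l_max + 1) ** 2


def real_sph_harm(l_max: int, vectors: np.ndarray) -> np.ndarray:
    """Real orthonormal spherical harmonics of unit(ized) direction vectors.

    Parameters
    ----------
    vectors : (..., 3) array
        Directions; need not be normalized (zero vectors are invalid).

    Returns
    -------
    (..., (l_max+1)**2) array, channels ordered by ``lm_index``.
    """
    v = np.asarray(vectors, dtype=float)
    r = np.linalg.norm(v, axis=-1)
    if np.any(r == 0.0):
        raise ValueError("cannot take the direction of a zero vector")
    unit = v / r[..., None]
    theta = np.arccos(np.clip(unit[..., 2], -1.0, 1.0))
    phi = np.arctan2(unit[..., 1], unit[..., 0])
    out = np.empty(v.shape[:-1] + (n_lm(l_max),))
    sqrt2 = np.sqrt(2.0)
    for l in range(l_max + 1):
        out[..., lm_index(l, 0)] = sph_harm_y(l, 0, theta, phi).real
        for m in range(1, l + 1):
            ylm = sph_harm_y(l, m, theta, phi)
            sign = (-1.0) ** m  # strips the Condon–Shortley phase
            out[..., lm_index(l, m)] = sqrt2 * sign * ylm.real
            out[..., lm_index(l, -m)] = sqrt2 * sign * ylm.imag
    return out


def sphere_grid(degree: int) -> tuple[np.ndarray, np.ndarray]:
    """Angular quadrature exact for spherical harmonics up to ``degree``.

    Product rule: Gauss–Legendre in cos(θ) × trapezoid in φ; returns unit
    vectors (M, 3) and weights summing to 4π.
    """
    n_t = degree // 2 + 1
    n_p = degree + 1
    u, wu = np.polynomial.legendre.leggauss(n_t)
    phi = 2.0 * np.pi * np.arange(n_p) / n_p
    st = np.sqrt(1.0 - u**2)
    dirs = np.empty((n_t, n_p, 3))
    dirs[..., 0] = st[:, None] * np.cos(phi)[None, :]
    dirs[..., 1] = st[:, None] * np.sin(phi)[None, :]
    dirs[..., 2] = u[:, None]
    w = np.broadcast_to(wu[:, None] * (2.0 * np.pi / n_p), (n_t, n_p))
    return dirs.reshape(-1, 3), w.reshape(-1).copy()


def ball_grid(
    r_cut: float, n_radial: int = 50, degree: int = 30
) -> tuple[np.ndarray, np.ndarray]:
    """3-D quadrature over the ball |r| ≤ r_cut.

    Gauss–Legendre radial nodes (the r² measure folded into the weights)
    times a :func:`sphere_grid`; returns points (M, 3) and weights such
    that Σ w_k f(x_k) ≈ ∫_ball f d³r.
    """
    x, wx = np.polynomial.legendre.leggauss(n_radial)
    r = 0.5 * r_cut * (x + 1.0)
    wr = 0.5 * r_cut * wx * r**2
    dirs, wang = sphere_grid(degree)
    pts = r[:, None, None] * dirs[None, :, :]
    w = wr[:, None] * wang[None, :]
    return pts.reshape(-1, 3), w.reshape(-1)
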