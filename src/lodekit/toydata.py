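"""Synthetic datasets with exact reference energies and forces.

Two families of data:

* periodic "toy" sets — cubic cells with randomly placed particles under
  a minimum-distance constraint, carrying either an overall neutral
  cloud of ±1 charges (ground truth: full Ewald electrostatics) or
  uniform attractive 1/r^6 dispersion (ground truth: real-space lattice
  sum with an integral tail correction);
* dimer binding curves — two rigid synthetic fragments of point sites
  whose leading multipole orders are chosen to realize a target
  asymptotic decay exponent p ∈ {1..6}, pulled apart along the line of
  the centers of mass, with a train/test split at a threshold
  separation and an optional dissociated (monomer-only) frame.

Electrostatic energies are in eV using the prefactor e²/(4πε₀) =
14.3996 eV·Å; dispersion uses C6 in eV·Å⁶ directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfc

from .fields import InteractionSpec, evaluate_field_periodic, kernel_fourier
from .structures import Structure, periodic_shifts

__all__ = [
    "COULOMB_EV_A",
    "ToyDatasetSpec",
    "BindingCurveSpec",
    "BindingFrame",
    "generate_toy_structures",
    "ewald_energy",
    "ewald_forces",
    "dispersion_energy",
    "dispersion_forces",
    "field_contracted_energy",
    "rocksalt_structure",
    "generate_binding_curves",
]

COULOMB_EV_A = 14.3996  # e²/(4πε₀) in eV·Å


# ---------------------------------------------------------------------------
# periodic toy sets
# ---------------------------------------------------------------------------


@dataclass
class ToyDatasetSpec:
    """Random periodic cells of hard-sphere-like particles.

    ``coulomb_pm1`` labels half the particles species "P" (+1) and half
    "N" (-1); ``dispersion_c6`` uses a single species "X" with unit
    weights. Cubic cell edges are drawn uniformly from ``cell_range``.
    """

    n_structures: int = 2000
    n_atoms: int = 64
    min_dist: float = 2.5
    cell_range: tuple[float, float] = (12.0, 18.0)
    interaction: str = "coulomb_pm1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.interaction not in ("coulomb_pm1", "dispersion_c6"):
            raise ValueError(f"unknown interaction {self.interaction!r}")
        if self.interaction == "coulomb_pm1" and self.n_atoms % 2:
            raise ValueError("coulomb_pm1 needs an even number of atoms")


_MAX_REJECT = 10_000


def _place_atoms(rng: np.random.Generator, n: int, edge: float, dmin: float):
    pos = np.empty((n, 3))
    placed = 0
    rejects = 0
    while placed < n:
        cand = rng.uniform(0.0, edge, size=3)
        if placed:
            diff = pos[:placed] - cand
            diff -= edge * np.round(diff / edge)
            if np.min(np.linalg.norm(diff, axis=1)) < dmin:
                rejects += 1
                if rejects >= _MAX_REJECT:
                    frac = n * (4.0 / 3.0) * np.pi * (dmin / 2) ** 3 / edge**3
                    raise RuntimeError(
                        f"packing infeasible: {rejects} consecutive rejections "
                        f"(packing fraction {frac:.2f} at edge {edge:.1f} Å)"
                    )
                continue
        pos[placed] = cand
        placed += 1
        rejects = 0
    return pos


def generate_toy_structures(spec: ToyDatasetSpec) -> list[Structure]:
    """Seeded rejection sampling; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(spec.n_structures):
        edge = rng.uniform(*spec.cell_range)
        pos = _place_atoms(rng, spec.n_atoms, edge, spec.min_dist)
        cell = np.eye(3) * edge
        if spec.interaction == "coulomb_pm1":
            half = spec.n_atoms // 2
            species = ["P"] * half + ["N"] * half
            weights = np.concatenate([np.ones(half), -np.ones(half)])
        else:
            species = ["X"] * spec.n_atoms
            weights = np.ones(spec.n_atoms)
        out.append(Structure(pos, species, cell, weights))
    return out


# ---------------------------------------------------------------------------
# electrostatic ground truth (full Ewald)
# ---------------------------------------------------------------------------


def _ewald_params(smearing: float, realspace_cutoff, k_cutoff):
    if realspace_cutoff is None:
        realspace_cutoff = 8.0 * smearing  # erfc(8/√2) ≈ 1e-15
    if k_cutoff is None:
        k_cutoff = 8.0 / smearing
    return realspace_cutoff, k_cutoff


def ewald_energy(
    structure: Structure,
    smearing: float = 1.0,
    k_cutoff: float | None = None,
    realspace_cutoff: float | None = None,
) -> float:
    """Exact point-charge electrostatic energy of a neutral periodic cell, eV.

    Standard Ewald split with Gaussian width σ: screened real-space part
    (erfc), reciprocal part using the smeared-Coulomb Fourier kernel, and
    the self term -Σ q²/(√(2π)σ). Tinfoil (neutralizing-background)
    convention; the result is independent of σ once both cutoffs are
    converged, which the defaults guarantee to ~1e-10.
    """
    if not structure.is_periodic:
        raise ValueError("Ewald sums need a periodic structure")
    q = structure.weights
    if abs(q.sum()) > 1e-10:
        raise ValueError("structure must be charge neutral (tinfoil convention)")
    rcut, kcut = _ewald_params(smearing, realspace_cutoff, k_cutoff)
    alpha = 1.0 / (np.sqrt(2.0) * smearing)
    pos = structure.positions

    e_real = 0.0
    for t in periodic_shifts(structure.cell, rcut):
        diff = pos[:, None, :] - pos[None, :, :] + t
        d = np.linalg.norm(diff, axis=-1)
        mask = (d > 1e-12) & (d <= rcut)
        dm = np.where(mask, d, 1.0)
        e_real += 0.5 * np.sum((q[:, None] * q[None, :]) * erfc(alpha * dm) / dm * mask)

    spec = InteractionSpec(p=1.0, smearing=smearing)
    fld = evaluate_field_periodic(structure, spec, kcut)
    e_recip = 0.5 * float(q @ fld.evaluate(pos))
    e_self = -np.sum(q**2) / (np.sqrt(2.0 * np.pi) * smearing)
    return COULOMB_EV_A * (e_real + e_recip + e_self)


def ewald_forces(
    structure: Structure,
    smearing: float = 1.0,
    k_cutoff: float | None = None,
    realspace_cutoff: float | None = None,
) -> np.ndarray:
    """Analytic forces -∂E/∂r_i of :func:`ewald_energy`, eV/Å, shape (N, 3)."""
    q = structure.weights
    rcut, kcut = _ewald_params(smearing, realspace_cutoff, k_cutoff)
    alpha = 1.0 / (np.sqrt(2.0) * smearing)
    pos = structure.positions
    forces = np.zeros_like(pos)
    for t in periodic_shifts(structure.cell, rcut):
        diff = pos[:, None, :] - pos[None, :, :] + t
        d = np.linalg.norm(diff, axis=-1)
        mask = (d > 1e-12) & (d <= rcut)
        dm = np.where(mask, d, 1.0)
        mag = (
            erfc(alpha * dm) / dm**2
            + (2.0 * alpha / np.sqrt(np.pi)) * np.exp(-((alpha * dm) ** 2)) / dm
        ) / dm
        pair = (q[:, None] * q[None, :]) * mag * mask
        forces += np.sum(pair[:, :, None] * diff, axis=1)
    spec = InteractionSpec(p=1.0, smearing=smearing)
    kv = np.asarray(
        evaluate_field_periodic(structure, spec, kcut)._kvecs
    )
    gk = kernel_fourier(spec, np.linalg.norm(kv, axis=1))
    sk = np.exp(-1j * kv @ pos.T) @ q
    vol = structure.volume
    phase = np.exp(-1j * kv @ pos.T)  # e^{-ik·r_i}, (nk, N)
    # F_iα = -(q_i/Ω) Σ_k ĝ(k) k_α Im[S(k)* e^{-ik·r_i}]
    forces -= (q[:, None] / vol) * np.einsum(
        "k,ka,ki->ia", gk, kv, (sk.conj()[:, None] * phase).imag
    )
    return COULOMB_EV_A * forces


def field_contracted_energy(
    structure: Structure, smearing: float, k_cutoff: float
) -> float:
    """½ Σ_i q_i V(r_i) minus the self term — the smeared total energy, eV.

    Ties the descriptor field and the Ewald ground truth to one
    implementation of electrostatics: for smearing small enough that no
    pair sits within the smearing range this equals :func:`ewald_energy`.
    """
    spec = InteractionSpec(p=1.0, smearing=smearing)
    fld = evaluate_field_periodic(structure, spec, k_cutoff)
    q = structure.weights
    v = fld.evaluate(structure.positions)
    e_self = np.sum(q**2) * np.sqrt(2.0 / np.pi) / (2.0 * smearing)
    return COULOMB_EV_A * (0.5 * float(q @ v) - e_self)


# ---------------------------------------------------------------------------
# dispersion ground truth (real-space lattice sum)
# ---------------------------------------------------------------------------


def dispersion_energy(
    structure: Structure, cutoff: float | None = None, c6: float = 1.0
) -> float:
    """Attractive pairwise -C6/r⁶ lattice energy with integral tail, eV.

    E = -½ Σ_i Σ_{j,images≠i} C6/d⁶ (d ≤ cutoff)  -  2π N ρ C6 / (3 cutoff³).

    The default cutoff of four cell edges converges the sum to ~1e-6
    relative for the toy densities.
    """
    if not structure.is_periodic:
        raise ValueError("dispersion lattice sum needs a periodic structure")
    pos = structure.positions
    n = len(structure)
    vol = structure.volume
    if cutoff is None:
        cutoff = 4.0 * vol ** (1.0 / 3.0)
    e = 0.0
    for t in periodic_shifts(structure.cell, cutoff):
        diff = pos[:, None, :] - pos[None, :, :] + t
        d2 = np.sum(diff * diff, axis=-1)
        mask = (d2 > 1e-20) & (d2 <= cutoff**2)
        d2 = np.where(mask, d2, 1.0)
        e -= 0.5 * c6 * np.sum(mask / d2**3)
    e -= 2.0 * np.pi * n * (n / vol) * c6 / (3.0 * cutoff**3)
    return float(e)


def dispersion_forces(
    structure: Structure, cutoff: float | None = None, c6: float = 1.0
) -> np.ndarray:
    """Analytic forces of :func:`dispersion_energy` (tail is force-free)."""
    pos = structure.positions
    if cutoff is None:
        cutoff = 4.0 * structure.volume ** (1.0 / 3.0)
    forces = np.zeros_like(pos)
    for t in periodic_shifts(structure.cell, cutoff):
        diff = pos[:, None, :] - pos[None, :, :] + t
        d2 = np.sum(diff * diff, axis=-1)
        mask = (d2 > 1e-20) & (d2 <= cutoff**2)
        d2 = np.where(mask, d2, 1.0)
        mag = -6.0 * c6 / d2**4 * mask  # -(1/d) dE_pair/dd
        forces += np.sum(mag[:, :, None] * diff, axis=1)
    return forces


def rocksalt_structure(lattice_constant: float = 5.0) -> Structure:
    """Conventional 8-atom rock-salt cell of ±1 charges (NaCl arrangement)."""
    a = lattice_constant
    frac = np.array(
        [
            [0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0.5],  # +1
            [0.5, 0, 0], [0, 0.5, 0], [0, 0, 0.5], [0.5, 0.5, 0.5],  # -1
        ]
    )
    species = ["P"] * 4 + ["N"] * 4
    weights = np.array([1.0] * 4 + [-1.0] * 4)
    return Structure(frac * a, species, np.eye(3) * a, weights)


# ---------------------------------------------------------------------------
# dimer binding curves
# ---------------------------------------------------------------------------


@dataclass
class BindingCurveSpec:
    """Synthetic dimer protocol with a controlled asymptotic exponent.

    ``decay_p`` selects the leading multipole orders of the two rigid
    fragments so that the cross-fragment interaction decays as
    1/r^{decay_p} (p = 6 uses pairwise C6 sites instead). The train/test
    split is decided solely by ``separation - r0 <= r_train``.
    """

    r0: float = 3.0
    r_max: float = 15.0
    n_points: int = 40
    decay_p: int = 1
    r_train: float = 4.0
    include_dissociated: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.decay_p <= 6:
            raise ValueError("decay_p must be in 1..6")
        if not self.r0 < self.r_max:
            raise ValueError("need r0 < r_max")


@dataclass
class BindingFrame:
    structure: Structure
    energy: float  # interaction energy (dimer minus monomers), eV
    forces: np.ndarray  # (N, 3), eV/Å, cross-fragment part
    split: str  # "train" | "test"
    separation: float  # COM distance, Å (inf for the dissociated frame)


def _linear_multipole(order: int, spacing: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Collinear site charges (±binomial) whose leading moment is a 2^order-pole.

    The alternating-binomial stencil is the discrete l-th derivative of a
    point charge, so every multipole below ``order`` vanishes exactly.
    """
    from math import comb

    k = np.arange(order + 1)
    charges = np.array([(-1.0) ** j * comb(order, j) for j in k])
    z = (k - order / 2.0) * spacing
    sites = np.zeros((order + 1, 3))
    sites[:, 2] = z
    return sites, charges


_FRAGMENTS = {
    # decay_p: (order of fragment A, order of fragment B); p = lA + lB + 1
    1: (0, 0), 2: (0, 1), 3: (1, 1), 4: (1, 2), 5: (2, 2),
}


def _cross_terms(pos_a, q_a, pos_b, q_b, c6: float):
    """Cross-fragment Coulomb + C6 energy and per-site forces."""
    diff = pos_a[:, None, :] - pos_b[None, :, :]
    d = np.linalg.norm(diff, axis=-1)
    qq = q_a[:, None] * q_b[None, :]
    e = COULOMB_EV_A * np.sum(qq / d) - c6 * np.sum(1.0 / d**6)
    mag = COULOMB_EV_A * qq / d**3 + 6.0 * c6 / d**8  # -(1/d) dE/dd per pair
    f_a = np.sum(mag[:, :, None] * diff, axis=1)
    return float(e), f_a, mag, diff


def generate_binding_curves(spec: BindingCurveSpec, seed: int = 0) -> list[BindingFrame]:
    """Dimer frames along the COM line with exact site–site energetics.

    The seed only perturbs the transverse placement of the fragment
    sites slightly (fragments stay rigid along the curve), so different
    seeds give slightly different but equally valid curves.
    """
    rng = np.random.default_rng(seed)
    if spec.decay_p == 6:
        sites_a = np.zeros((2, 3))
        sites_a[1, 2] = 0.5
        q_a = np.zeros(2)
        sites_b, q_b = sites_a.copy(), np.zeros(2)
        c6 = 1.0
    else:
        la, lb = _FRAGMENTS[spec.decay_p]
        sites_a, q_a = _linear_multipole(la)
        sites_b, q_b = _linear_multipole(lb)
        c6 = 0.0
    for s in (sites_a, sites_b):
        s[:, :2] += rng.normal(scale=0.02, size=(s.shape[0], 2))
        s -= s.mean(axis=0)

    seps = np.linspace(spec.r0, spec.r_max, spec.n_points)
    frames: list[BindingFrame] = []
    for r in seps:
        pa = sites_a.copy()
        pb = sites_b + np.array([0.0, 0.0, r])
        e, f_a, mag, diff = _cross_terms(pa, q_a, pb, q_b, c6)
        f_b = -np.sum(mag[:, :, None] * diff, axis=0)
        pos = np.vstack([pa, pb])
        species = ["A"] * len(pa) + ["B"] * len(pb)
        st = Structure(pos, species, None, np.concatenate([q_a, q_b]))
        split = "train" if (r - spec.r0) <= spec.r_train else "test"
        frames.append(BindingFrame(st, e, np.vstack([f_a, f_b]), split, float(r)))
    if spec.include_dissociated:
        st = Structure(sites_a.copy(), ["A"] * len(sites_a), None, q_a.copy())
        frames.append(
            BindingFrame(st, 0.0, np.zeros_like(sites_a), "train", float("inf"))
        )
    return frames
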