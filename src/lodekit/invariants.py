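"""Rotationally invariant features built from expansion coefficients.

Two constructions are provided:

* the radial spectrum — just the l = m = 0 coefficients, linear in the
  field, which is all the toy-system linear models need;
* the power spectrum — the SOAP-style second-order contraction

      p_{an, bn', l} = Σ_m A_{i,anlm} B_{i,bn'lm} / √(2l+1),

  between two coefficient blocks sharing centers and l_max. Taking A a
  short-range density block and B a long-range block yields the
  multiscale features; A = B on the long-range block gives a
  second-order invariant of the far field.

Both are invariant under rigid rotations/translations and permutations
of same-species atoms, and carry an index map naming every column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lode import CoefficientBlock
from .spherical import lm_index

__all__ = ["InvariantVector", "radial_spectrum", "power_spectrum"]


@dataclass
class InvariantVector:
    """Per-center feature matrix plus a name for every column."""

    values: np.ndarray  # (n_centers, n_features)
    index: list[tuple]  # one tuple per column

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def structure_sum(self) -> np.ndarray:
        """Sum over centers — the per-structure feature vector."""
        return self.values.sum(axis=0)

    @staticmethod
    def concatenate(parts: list["InvariantVector"]) -> "InvariantVector":
        return InvariantVector(
            np.concatenate([p.values for p in parts], axis=1),
            [t for p in parts for t in p.index],
        )


def radial_spectrum(block: CoefficientBlock) -> InvariantVector:
    """Extract the l = m = 0 coefficients per (neighbor species, n)."""
    kind = block.meta.get("kind", "coeff")
    v000 = block.values[..., lm_index(0, 0)]  # (N, ch, n)
    n_at = v000.shape[0]
    index = [
        (kind, a, n)
        for a in block.species_channels
        for n in range(block.basis.n_max)
    ]
    return InvariantVector(v000.reshape(n_at, -1), index)


def power_spectrum(
    block_a: CoefficientBlock, block_b: CoefficientBlock | None = None
) -> InvariantVector:
    """Invariant contraction of two blocks over m, per l channel.

    With ``block_b`` omitted (or identical to ``block_a``) only the
    upper triangle over the combined (species, n) index is kept, with
    off-diagonal entries scaled by √2 so the Euclidean norm of the
    feature vector is preserved.
    """
    same = block_b is None or block_b is block_a
    b = block_a if same else block_b
    if block_a.n_centers != b.n_centers:
        raise ValueError("blocks must share centers")
    if block_a.l_max != b.l_max:
        raise ValueError("blocks must share l_max")
    n_at = block_a.n_centers
    ka = block_a.meta.get("kind", "A")
    kb = b.meta.get("kind", "B")
    feats, index = [], []
    for l in range(block_a.l_max + 1):
        sl = slice(lm_index(l, -l), lm_index(l, l) + 1)
        pa = block_a.values[..., sl]  # (N, chA, nA, 2l+1)
        pb = b.values[..., sl]
        prod = np.einsum("ianm,ibkm->ianbk", pa, pb) / np.sqrt(2.0 * l + 1.0)
        cha, na = prod.shape[1], prod.shape[2]
        chb, nb = prod.shape[3], prod.shape[4]
        for ia in range(cha):
            for n in range(na):
                for ib in range(chb):
                    for k in range(nb):
                        if same and (ib, k) < (ia, n):
                            continue
                        col = prod[:, ia, n, ib, k]
                        if same and (ib, k) != (ia, n):
                            col = np.sqrt(2.0) * col
                        feats.append(col)
                        index.append(
                            (
                                ka, block_a.species_channels[ia], n,
                                kb, b.species_channels[ib], k, l,
                            )
                        )
    return InvariantVector(np.stack(feats, axis=1), index)
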