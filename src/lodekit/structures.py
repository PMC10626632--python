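"""Atomic structure container and extended-XYZ input/output.

A :class:`Structure` holds Cartesian positions (Å), opaque species labels,
an optional 3x3 periodic cell and per-atom scalar weights (pseudo-charges).
Weights default to 1 and carry the ±1 charges of the charged toy systems;
the math never interprets species labels numerically.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Structure",
    "read_structures",
    "write_structures",
    "minimum_image_distances",
    "periodic_shifts",
]


class ParseError(ValueError):
    """Raised when an extended-XYZ file cannot be parsed."""


@dataclass
class Structure:
    """A set of atoms, optionally periodic.

    Parameters
    ----------
    positions : (N, 3) float array
        Cartesian coordinates in Å.
    species : sequence of str
        Chemical labels, one per atom. Opaque: only used to group atoms
        into channels.
    cell : (3, 3) float array or None
        Rows are the lattice vectors in Å. ``None`` marks an aperiodic
        (cluster) structure.
    weights : (N,) float array or None
        Dimensionless pseudo-charges entering the atom density. Defaults
        to 1 for every atom.
    extra : dict
        Per-atom or per-frame metadata carried through I/O round-trips.
    """

    positions: np.ndarray
    species: list[str]
    cell: np.ndarray | None = None
    weights: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")
        n = self.positions.shape[0]
        if n < 1:
            raise ValueError("a structure needs at least one atom")
        self.species = [str(s) for s in self.species]
        if len(self.species) != n:
            raise ValueError("species and positions length mismatch")
        if self.cell is not None:
            self.cell = np.asarray(self.cell, dtype=float).reshape(3, 3)
            if np.linalg.det(self.cell) <= 0.0:
                raise ValueError("cell must have strictly positive determinant")
        if self.weights is None:
            self.weights = np.ones(n)
        else:
            self.weights = np.asarray(self.weights, dtype=float).reshape(n)

    # -- basic queries -------------------------------------------------
    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def is_periodic(self) -> bool:
        return self.cell is not None

    @property
    def volume(self) -> float:
        if self.cell is None:
            raise ValueError("aperiodic structure has no cell volume")
        return float(np.linalg.det(self.cell))

    def species_set(self) -> list[str]:
        """Distinct species labels in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.species:
            seen.setdefault(s)
        return list(seen)

    def copy(self) -> "Structure":
        return Structure(
            self.positions.copy(),
            list(self.species),
            None if self.cell is None else self.cell.copy(),
            self.weights.copy(),
            dict(self.extra),
        )


# ---------------------------------------------------------------------------
# extended-XYZ I/O
# ---------------------------------------------------------------------------

_KEYVAL = re.compile(
    r"""(\S+)=(?:"([^"]*)"|(\S+))"""  # key="quoted value" | key=bare
)


def _parse_comment(line: str) -> dict:
    out = {}
    for m in _KEYVAL.finditer(line):
        key = m.group(1)
        val = m.group(2) if m.group(2) is not None else m.group(3)
        out[key] = val
    return out


def _parse_properties(prop: str) -> list[tuple[str, str, int]]:
    toks = prop.split(":")
    if len(toks) % 3 != 0:
        raise ParseError(f"malformed Properties string: {prop!r}")
    cols = []
    for i in range(0, len(toks), 3):
        cols.append((toks[i], toks[i + 1], int(toks[i + 2])))
    return cols


def read_structures(path) -> list[Structure]:
    """Read a (multi-frame) extended-XYZ file.

    Supports the ``Lattice="ax ay az bx ..."`` header and
    ``Properties=species:S:1:pos:R:3[:charge:R:1:...]`` per-atom columns.
    A ``charge`` column populates :attr:`Structure.weights`; any other
    per-atom column is preserved in ``extra`` and written back on output.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    structures: list[Structure] = []
    i = 0
    frame = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError as exc:
            raise ParseError(f"frame {frame}: bad atom count line {lines[i]!r}") from exc
        if i + 1 + natoms > len(lines):
            raise ParseError(f"frame {frame}: truncated ({natoms} atoms declared)")
        header = _parse_comment(lines[i + 1])
        cell = None
        if "Lattice" in header:
            vals = np.fromstring(header["Lattice"], sep=" ")
            if vals.size != 9:
                raise ParseError(f"frame {frame}: Lattice needs 9 numbers")
            cell = vals.reshape(3, 3)
        cols = _parse_properties(header.get("Properties", "species:S:1:pos:R:3"))
        species: list[str] = []
        pos = np.zeros((natoms, 3))
        weights = None
        extra_cols: dict[str, list] = {
            name: [] for name, _, _ in cols if name not in ("species", "pos", "charge")
        }
        for a in range(natoms):
            toks = lines[i + 2 + a].split()
            want = sum(c for _, _, c in cols)
            if len(toks) < want:
                raise ParseError(
                    f"frame {frame}: atom {a} has {len(toks)} fields, expected {want}"
                )
            off = 0
            for name, kind, count in cols:
                chunk = toks[off : off + count]
                off += count
                if name == "species":
                    species.append(chunk[0])
                elif name == "pos":
                    pos[a] = [float(x) for x in chunk]
                elif name == "charge":
                    if weights is None:
                        weights = np.zeros(natoms)
                    weights[a] = float(chunk[0])
                else:
                    cast = float if kind == "R" else (int if kind == "I" else str)
                    extra_cols[name].append(
                        cast(chunk[0]) if count == 1 else [cast(x) for x in chunk]
                    )
        extra = {}
        for key, val in header.items():
            if key not in ("Lattice", "Properties"):
                extra[key] = val
        for name in extra_cols:
            extra["col:" + name] = np.asarray(extra_cols[name])
        structures.append(Structure(pos, species, cell, weights, extra))
        i += 2 + natoms
        frame += 1
    return structures


def write_structures(path, structures) -> None:
    """Write structures as extended XYZ (inverse of :func:`read_structures`)."""
    if isinstance(structures, Structure):
        structures = [structures]
    with open(path, "w") as fh:
        for st in structures:
            fh.write(f"{len(st)}\n")
            fields = ["species:S:1", "pos:R:3", "charge:R:1"]
            col_names = [k[4:] for k in st.extra if k.startswith("col:")]
            for name in col_names:
                arr = np.asarray(st.extra["col:" + name])
                kind = "R" if np.issubdtype(arr.dtype, np.floating) else (
                    "I" if np.issubdtype(arr.dtype, np.integer) else "S"
                )
                width = 1 if arr.ndim == 1 else arr.shape[1]
                fields.append(f"{name}:{kind}:{width}")
            parts = []
            if st.cell is not None:
                lat = " ".join(f"{x:.14g}" for x in st.cell.ravel())
                parts.append(f'Lattice="{lat}"')
            parts.append("Properties=" + ":".join(fields))
            for key, val in st.extra.items():
                if not key.startswith("col:"):
                    sval = str(val)
                    parts.append(f'{key}="{sval}"' if " " in sval else f"{key}={sval}")
            fh.write(" ".join(parts) + "\n")
            for a in range(len(st)):
                row = [st.species[a]] + [f"{x:.14g}" for x in st.positions[a]]
                row.append(f"{st.weights[a]:.14g}")
                for name in col_names:
                    arr = np.asarray(st.extra["col:" + name])
                    vals = np.atleast_1d(arr[a])
                    row += [f"{v:.14g}" if not isinstance(v, str) else v for v in vals]
                fh.write(" ".join(row) + "\n")


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def minimum_image_distances(structure: Structure) -> np.ndarray:
    """N×N matrix of distances; nearest periodic image when a cell exists.

    For strongly skewed cells the nearest image is searched over the
    27 neighbouring cells of the fractional wrap, which is exact for any
    cell whose reduced basis is not pathological (all cells here are
    cubic or near-cubic).
    """
    pos = structure.positions
    diff = pos[:, None, :] - pos[None, :, :]
    if structure.cell is None:
        return np.linalg.norm(diff, axis=-1)
    cell = structure.cell
    frac = diff @ np.linalg.inv(cell)
    frac -= np.round(frac)
    shifts = np.array(
        [(a, b, c) for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)]
    )
    cand = (frac[..., None, :] + shifts) @ cell  # (N, N, 27, 3)
    d = np.linalg.norm(cand, axis=-1).min(axis=-1)
    np.fill_diagonal(d, 0.0)
    return d


def periodic_shifts(cell: np.ndarray, cutoff: float) -> np.ndarray:
    """All lattice translation vectors with |t| possibly ≤ cutoff.

    Returns every integer combination of the cell rows inside a bounding
    box guaranteed to contain the sphere of radius ``cutoff`` (callers
    filter by actual pair distance).
    """
    inv = np.linalg.inv(cell)
    # number of cells needed along each direction: cutoff / spacing
    heights = 1.0 / np.linalg.norm(inv, axis=0)  # perpendicular spacings
    nmax = np.ceil(cutoff / heights).astype(int)
    rng = [np.arange(-n, n + 1) for n in nmax]
    grid = np.stack(np.meshgrid(*rng, indexing="ij"), axis=-1).reshape(-1, 3)
    return grid @ cell
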