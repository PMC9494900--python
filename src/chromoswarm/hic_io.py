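"""Reading Hi-C contact matrices and reading/writing 3D bead structures.

Two matrix dialects are supported:

* a dense whitespace/comma-delimited square ``n x n`` matrix of interaction
  frequencies (IF), and
* a 3-column sparse list ``pos_i pos_j IF`` where the first two columns are
  either genomic start positions (mapped to bins as ``floor(pos/resolution)``)
  or pre-computed bin indices.

Structures are written as PDB bead models (one ATOM record per genomic bin,
CONECT records chaining consecutive bins) or as 4-column ``bin x y z`` text,
and read back from either format.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ContactMatrix",
    "Structure",
    "ParseError",
    "ValidationError",
    "read_contact_matrix",
    "read_structure",
    "write_structure_pdb",
    "write_structure_xyz",
]

#: relative tolerance beyond which a square input matrix is rejected as
#: asymmetric rather than silently averaged
SYMMETRY_RTOL = 1e-6

_DELIM = re.compile(r"[\s,]+")


class ParseError(ValueError):
    """Raised when an input file cannot be tokenized into the expected shape."""


class ValidationError(ValueError):
    """Raised when parsed values violate a domain invariant."""


@dataclass
class ContactMatrix:
    """Symmetric nonnegative interaction-frequency matrix over genomic bins.

    Parameters
    ----------
    values
        ``(n, n)`` array of interaction frequencies ``IF(i, j)``.
    resolution
        Bin width in base pairs, if known.
    bin_ids
        Ordered bin labels; defaults to ``0..n-1``.
    """

    values: np.ndarray
    resolution: Optional[int] = None
    bin_ids: Sequence = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValidationError(
                f"contact matrix must be square, got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("contact matrix contains non-finite entries")
        if np.any(self.values < 0):
            raise ValidationError("contact matrix contains negative entries")
        scale = float(np.abs(self.values).max()) or 1.0
        if not np.allclose(self.values, self.values.T, atol=SYMMETRY_RTOL * scale):
            raise ValidationError(
                f"matrix asymmetric beyond relative tolerance {SYMMETRY_RTOL}"
            )
        # exact symmetry downstream (wish-distance pairs use the upper triangle)
        self.values = 0.5 * (self.values + self.values.T)
        if self.resolution is not None and self.resolution <= 0:
            raise ValidationError("resolution must be a positive integer")
        if self.bin_ids is None:
            self.bin_ids = list(range(self.n_bins))
        elif len(self.bin_ids) != self.n_bins:
            raise ValidationError("bin_ids length does not match matrix size")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    def zero_bins(self) -> np.ndarray:
        """Indices of bins with no off-diagonal contacts (kept, but they
        contribute no wish distances)."""
        off = self.values.copy()
        np.fill_diagonal(off, 0.0)
        return np.flatnonzero(off.sum(axis=1) == 0)


@dataclass
class Structure:
    """Ordered 3D bead model: one ``(x, y, z)`` bead per genomic bin."""

    coords: np.ndarray
    labels: Sequence = field(default=None)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError(
                f"coords must have shape (n, 3), got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("structure contains non-finite coordinates")
        if self.labels is None:
            self.labels = list(range(self.n_beads))
        elif len(self.labels) != self.n_beads:
            raise ValidationError("labels length does not match bead count")

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]


def _tokenize(path) -> list[tuple[int, list[str]]]:
    """Return (1-based line number, fields) for each non-empty, non-comment line."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append((lineno, [f for f in _DELIM.split(line) if f]))
    return rows


def _parse_floats(fields: list[str], lineno: int) -> list[float]:
    try:
        return [float(f) for f in fields]
    except ValueError as exc:
        raise ParseError(f"non-numeric value on line {lineno}: {exc}") from None


def read_contact_matrix(path, resolution: Optional[int] = None) -> ContactMatrix:
    """Read a contact matrix from dense square or 3-column sparse text.

    The dialect is auto-detected from the column count of the first data
    row: ``n`` columns over ``n`` rows is a square matrix; 3 columns is a
    sparse ``pos_i pos_j IF`` list (a 3x3 symmetric file is read as square).
    Sparse genomic positions are mapped to bins as ``floor(pos/resolution)``
    with the minimum observed bin shifted to index 0; without a resolution
    the first two columns must already be integer bin indices. Pairs listed
    twice must agree; unlisted sparse pairs are 0.
    """
    rows = _tokenize(path)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    ncols = len(rows[0][1])
    if ncols == 3 and len(rows) == 3:
        try:
            return _read_square(rows, resolution)
        except (ParseError, ValidationError):
            return _read_sparse(rows, resolution)
    if ncols == 3:
        return _read_sparse(rows, resolution)
    return _read_square(rows, resolution)


def _read_square(rows, resolution) -> ContactMatrix:
    n = len(rows[0][1])
    data = []
    for lineno, fields in rows:
        if len(fields) != n:
            raise ParseError(
                f"ragged row on line {lineno}: expected {n} fields, got {len(fields)}"
            )
        data.append(_parse_floats(fields, lineno))
    if len(data) != n:
        raise ParseError(f"square matrix has {len(data)} rows but {n} columns")
    return ContactMatrix(np.array(data), resolution=resolution)


def _read_sparse(rows, resolution) -> ContactMatrix:
    recs = []
    for lineno, fields in rows:
        if len(fields) != 3:
            raise ParseError(
                f"ragged row on line {lineno}: expected 3 fields, got {len(fields)}"
            )
        a, b, v = _parse_floats(fields, lineno)
        if v < 0:
            raise ValidationError(f"negative IF on line {lineno}")
        recs.append((a, b, v, lineno))

    pos = np.array([(r[0], r[1]) for r in recs])
    if resolution is not None:
        bins = np.floor(pos / resolution).astype(int)
    else:
        if not np.allclose(pos, np.round(pos)):
            raise ValidationError(
                "sparse positions are not integer bin indices; pass a resolution"
            )
        bins = np.round(pos).astype(int)
    bins -= bins.min()
    n = int(bins.max()) + 1

    values = np.zeros((n, n))
    seen: dict[tuple[int, int], float] = {}
    for (i, j), (_, _, v, lineno) in zip(bins, recs):
        key = (min(i, j), max(i, j))
        if key in seen and not np.isclose(seen[key], v):
            raise ValidationError(
                f"conflicting duplicate entry for pair {key} on line {lineno}: "
                f"{seen[key]} vs {v}"
            )
        seen[key] = v
        values[i, j] = v
        values[j, i] = v
    return ContactMatrix(values, resolution=resolution)


# --- structure I/O -----------------------------------------------------------

#: PDB 8.3 coordinate fields overflow beyond +/-9999.999; one uniform rescale
#: keeps the written model within range (shape is what matters downstream)
_PDB_COORD_MAX = 999.0


def write_structure_pdb(structure: Structure, path) -> None:
    """Write a bead-polymer PDB: one CA ATOM per bin plus CONECT chaining."""
    coords = structure.coords
    extent = np.abs(coords).max() if coords.size else 0.0
    if extent > _PDB_COORD_MAX:
        coords = coords * (_PDB_COORD_MAX / extent)
    lines = []
    for serial, (x, y, z) in enumerate(coords, start=1):
        lines.append(
            f"ATOM  {serial:5d}  CA  GLY A{serial % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    for serial in range(1, structure.n_beads):
        lines.append(f"CONECT{serial:5d}{serial + 1:5d}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_structure_xyz(structure: Structure, path) -> None:
    """Write 4-column ``bin x y z`` text."""
    lines = [
        f"{label}\t{x:.6f}\t{y:.6f}\t{z:.6f}"
        for label, (x, y, z) in zip(structure.labels, structure.coords)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_structure(path) -> Structure:
    """Read a structure from a PDB file or from 3/4-column XYZ text."""
    text = Path(path).read_text()
    if "ATOM" in text or "HETATM" in text:
        coords = [
            [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            for line in text.splitlines()
            if line.startswith(("ATOM  ", "HETATM"))
        ]
        if not coords:
            raise ValidationError(f"{path}: no ATOM records")
        return Structure(np.array(coords))

    rows = _tokenize(path)
    if not rows:
        raise ValidationError(f"{path}: empty structure file")
    width = len(rows[0][1])
    if width not in (3, 4):
        raise ParseError(
            f"structure text must have 3 or 4 columns, got {width} on line {rows[0][0]}"
        )
    coords, labels = [], []
    for lineno, fields in rows:
        if len(fields) != width:
            raise ParseError(f"ragged row on line {lineno}")
        vals = _parse_floats(fields, lineno)
        if width == 4:
            labels.append(fields[0])
            coords.append(vals[1:])
        else:
            coords.append(vals)
    return Structure(np.array(coords), labels=labels or None)
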