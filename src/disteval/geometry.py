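"""Core structural data model: parsed chains, distance maps, sequence separation.

Residue indices are 1-based at every public interface.  A residue is *valid*
when a representative atom (CB, or CA for glycine / CB-less residues) could be
resolved; pairs touching an invalid residue are excluded from all downstream
metric denominators rather than imputed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ProteinRecord",
    "DistanceMap",
    "SeparationClass",
    "DegenerateStructureError",
    "true_distance_map",
    "separation_class",
    "effective_length",
]


class DegenerateStructureError(ValueError):
    """Raised when a structure has fewer than two valid residues."""


class SeparationClass(enum.Enum):
    """Sequence-separation range of a residue pair, determined by ``|i - j|``.

    local: |i-j| < 6;  short: 6 <= |i-j| < 12;  medium: 12 <= |i-j| < 24;
    long: |i-j| >= 24.
    """

    LOCAL = "local"
    SHORT = "short"
    MEDIUM = "medium"
    LONG = "long"


#: All four classes, convenient for "no separation filter" metric calls.
ALL_CLASSES = frozenset(SeparationClass)

#: Classes used for the headline precision/MAE variants.
MEDIUM_LONG = frozenset({SeparationClass.MEDIUM, SeparationClass.LONG})
LONG_ONLY = frozenset({SeparationClass.LONG})


@dataclass
class ProteinRecord:
    """A parsed protein chain reduced to one representative atom per residue.

    Attributes
    ----------
    sequence : str
        One-letter amino-acid sequence of length L ('X' for unknown residues).
    coords : (L, 3) ndarray
        Representative-atom coordinates in Angstroms; NaN where invalid.
    valid : (L,) ndarray of bool
        True where a representative atom exists.
    """

    sequence: str
    coords: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        L = len(self.sequence)
        if self.coords.shape != (L, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match sequence length {L}"
            )
        if self.valid.shape != (L,):
            raise ValueError(
                f"valid mask shape {self.valid.shape} does not match sequence length {L}"
            )
        if not np.all(np.isfinite(self.coords[self.valid])):
            raise ValueError("coordinates of valid residues must be finite")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class DistanceMap:
    """Square matrix of inter-residue distances with a usability mask.

    Only the upper triangle (i < j, 1-based exclusive of the diagonal) is ever
    consulted by metrics and visualization; the lower triangle is kept purely
    as a mirrored convenience and its corruption must not change any result.

    Attributes
    ----------
    values : (L, L) ndarray
        Distances in Angstroms (content of masked cells is unspecified).
    mask : (L, L) ndarray of bool
        True where the cell is usable.  The diagonal is always masked.
    """

    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"distance matrix must be square, got {self.values.shape}")
        if self.mask is None:
            self.mask = np.isfinite(self.values) & (self.values > 0)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values shape")
        np.fill_diagonal(self.mask, False)

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def L(self) -> int:
        return self.values.shape[0]

    def upper_pairs(self):
        """Yield ``(i, j, distance)`` for unmasked upper-triangle cells, 1-based."""
        iu, ju = np.triu_indices(self.L, k=1)
        keep = self.mask[iu, ju]
        for a, b in zip(iu[keep], ju[keep]):
            yield int(a) + 1, int(b) + 1, float(self.values[a, b])

    def copy(self) -> "DistanceMap":
        return DistanceMap(self.values.copy(), self.mask.copy())


def true_distance_map(rec: ProteinRecord) -> DistanceMap:
    """Euclidean representative-atom distance map of a parsed chain.

    Pairs touching an invalid residue are masked.  Raises
    :class:`DegenerateStructureError` for chains with < 2 valid residues.
    """
    if rec.n_valid < 2:
        raise DegenerateStructureError(
            f"need at least 2 valid residues, structure has {rec.n_valid}"
        )
    coords = np.where(rec.valid[:, None], rec.coords, 0.0)
    diff = coords[:, None, :] - coords[None, :, :]
    values = np.sqrt((diff**2).sum(axis=-1))
    mask = rec.valid[:, None] & rec.valid[None, :]
    np.fill_diagonal(mask, False)
    return DistanceMap(values, mask)


def separation_class(i: int, j: int) -> SeparationClass:
    """Classify the pair ``(i, j)`` by sequence separation ``|i - j|``."""
    if i == j:
        raise ValueError("separation class is undefined for i == j")
    s = abs(i - j)
    if s < 6:
        return SeparationClass.LOCAL
    if s < 12:
        return SeparationClass.SHORT
    if s < 24:
        return SeparationClass.MEDIUM
    return SeparationClass.LONG


def effective_length(seq_len: int, n_valid: int) -> int:
    """L used for top-L/top-L/5 cutoffs: min(sequence length, valid residues)."""
    if seq_len < 1 or n_valid < 1:
        raise ValueError(f"lengths must be positive, got {seq_len}, {n_valid}")
    return min(int(seq_len), int(n_valid))
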