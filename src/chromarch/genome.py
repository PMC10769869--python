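"""Circular-genome coordinate arithmetic.

All circular bookkeeping (binning, coordinate shift, wrap-around
distances) lives here so that the rest of the package never does modular
arithmetic ad hoc.  The genome is a closed circle of ``length_bp`` base
pairs; analyses run in a shifted coordinate system (``shift_bp``) so
that, e.g., coordinates can be made to start at the first restriction
site of the enzyme used in the 3C protocol.

Conventions
-----------
* Internal coordinates are 0-based, half-open, in the *shifted* frame.
* Bins tile the circle from coordinate 0 in steps of ``bin_size_bp``;
  when the length is not a multiple of the bin size the final bin is a
  short bin and keeps its true midpoint.
* A circular interval is a pair ``(start, end)`` with
  ``0 <= start < L`` and ``start < end <= start + L``; ``end > L``
  means the interval wraps past the origin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["CircularGenome"]


@dataclass(frozen=True)
class CircularGenome:
    """Geometry of a circular chromosome.

    Parameters
    ----------
    length_bp:
        Total chromosome length in base pairs.
    bin_size_bp:
        Width of the non-overlapping analysis bins.
    shift_bp:
        Offset subtracted from annotated coordinates before binning
        (0 <= shift_bp < length_bp).
    origins_bp:
        Replication-origin positions (shifted frame), each in
        ``[0, length_bp)``.
    """

    length_bp: int
    bin_size_bp: int
    shift_bp: int = 0
    origins_bp: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.length_bp <= 0:
            raise ValueError("length_bp must be positive")
        if self.bin_size_bp < 1:
            raise ValueError("bin_size_bp must be >= 1")
        if not (0 <= self.shift_bp < self.length_bp):
            raise ValueError("shift_bp must satisfy 0 <= shift_bp < length_bp")
        object.__setattr__(self, "origins_bp", tuple(int(o) for o in self.origins_bp))
        for o in self.origins_bp:
            if not (0 <= o < self.length_bp):
                raise ValueError(f"origin {o} outside [0, {self.length_bp})")

    @property
    def n_bins(self) -> int:
        return math.ceil(self.length_bp / self.bin_size_bp)

    def shift(self, pos_bp):
        """Map annotated coordinates into the shifted frame (mod L)."""
        return (np.asarray(pos_bp) - self.shift_bp) % self.length_bp

    def bin_of(self, pos_bp):
        """Bin index of a (shifted-frame) position; applies the shift."""
        pos = np.asarray(pos_bp)
        if np.any(pos < 0):
            raise ValueError("negative position")
        if np.any(pos >= self.length_bp):
            raise ValueError("position beyond genome length")
        return self.shift(pos) // self.bin_size_bp

    def bin_start_bp(self, b):
        return np.asarray(b) * self.bin_size_bp

    def bin_end_bp(self, b):
        return np.minimum((np.asarray(b) + 1) * self.bin_size_bp, self.length_bp)

    @property
    def bin_midpoints_bp(self) -> np.ndarray:
        b = np.arange(self.n_bins)
        return (self.bin_start_bp(b) + self.bin_end_bp(b)) / 2.0

    def circular_distance_bp(self, a, b):
        d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))
        return np.minimum(d, self.length_bp - d)

    def bin_distance_bins(self, i, j):
        d = np.abs(np.asarray(i) - np.asarray(j))
        return np.minimum(d, self.n_bins - d)

    def bin_distance_matrix_bins(self) -> np.ndarray:
        """B x B matrix of circular bin separations."""
        idx = np.arange(self.n_bins)
        return self.bin_distance_bins(idx[:, None], idx[None, :])

    def bin_distance_matrix_bp(self) -> np.ndarray:
        """B x B matrix of circular bp distances between bin midpoints."""
        mid = self.bin_midpoints_bp
        return self.circular_distance_bp(mid[:, None], mid[None, :])
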