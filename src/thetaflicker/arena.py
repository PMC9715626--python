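"""Square arena geometry and position binning.

The recording environment is a square open-field arena discretised into a
regular grid of square position bins (default 60 cm side, 3 cm bins, i.e. a
20 x 20 grid).  Bins are half-open intervals ``[k*b, (k+1)*b)`` in both
coordinates, 0-based, with the origin at the arena corner.  Flat bin indices
are row-major with rows indexed by y: ``flat = iy * n + ix``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Arena"]


@dataclass(frozen=True)
class Arena:
    """Geometry of a square recording arena.

    Parameters
    ----------
    side_cm : float
        Side length of the square arena in cm.
    bin_cm : float
        Side length of a square position bin in cm.  Must divide ``side_cm``.
    """

    side_cm: float = 60.0
    bin_cm: float = 3.0

    def __post_init__(self) -> None:
        if self.side_cm <= 0 or self.bin_cm <= 0:
            raise ValueError("side_cm and bin_cm must be positive")
        n = self.side_cm / self.bin_cm
        if abs(n - round(n)) > 1e-9:
            raise ValueError("side_cm must be divisible by bin_cm")
        if round(n) < 2:
            raise ValueError("arena must have at least 2 bins per side")

    @property
    def n_bins(self) -> int:
        """Number of bins per side."""
        return int(round(self.side_cm / self.bin_cm))

    @property
    def n_bins_total(self) -> int:
        return self.n_bins * self.n_bins

    def bin_index(self, x, y):
        """Map coordinates (cm) to integer bin indices ``(ix, iy)``.

        Points exactly on the far edge are folded into the last bin.
        """
        n = self.n_bins
        ix = np.clip(np.floor(np.asarray(x) / self.bin_cm).astype(int), 0, n - 1)
        iy = np.clip(np.floor(np.asarray(y) / self.bin_cm).astype(int), 0, n - 1)
        return ix, iy

    def flat_index(self, x, y):
        """Row-major flat bin index ``iy * n + ix`` for coordinates in cm."""
        ix, iy = self.bin_index(x, y)
        return iy * self.n_bins + ix

    def bin_centers(self) -> np.ndarray:
        """Centres of all bins, shape ``(n_bins_total, 2)`` in flat order."""
        n = self.n_bins
        c = (np.arange(n) + 0.5) * self.bin_cm
        xx, yy = np.meshgrid(c, c)  # rows are y
        return np.column_stack([xx.ravel(), yy.ravel()])

    def contains(self, x, y) -> np.ndarray:
        return (
            (np.asarray(x) >= 0)
            & (np.asarray(x) <= self.side_cm)
            & (np.asarray(y) >= 0)
            & (np.asarray(y) <= self.side_cm)
        )
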