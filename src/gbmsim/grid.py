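"""Rectangular 2D grid at MRI resolution.

One grid cell is one virtual-MRI pixel of about 3 mm^2, so the default
spacing is h = sqrt(3) mm.  Boundaries are no-flux everywhere (the skull is
a barrier).  The tissue is homogeneous; any spatial structure enters only
through the concentration fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["Grid"]


@dataclass(frozen=True)
class Grid:
    """nx-by-ny grid with spacing ``h`` in mm; boundary is no-flux."""

    nx: int = 120
    ny: int = 120
    h: float = math.sqrt(3.0)

    def __post_init__(self) -> None:
        if self.nx < 3 or self.ny < 3:
            raise ValueError("grid must be at least 3x3")
        if not (self.h > 0):
            raise ValueError("grid spacing h must be positive")

    @property
    def shape(self) -> tuple:
        return (self.nx, self.ny)

    @property
    def pixel_area(self) -> float:
        """Area of one pixel in mm^2 (~3 mm^2 at the default spacing)."""
        return self.h * self.h

    @property
    def n_pixels(self) -> int:
        return self.nx * self.ny

    @property
    def extent_mm(self) -> tuple:
        return (self.nx * self.h, self.ny * self.h)

    def radius_mm(self, center: tuple | None = None) -> np.ndarray:
        """Distance of each pixel center from ``center`` (default: domain center)."""
        if center is None:
            center = ((self.nx - 1) / 2.0, (self.ny - 1) / 2.0)
        ix, iy = np.meshgrid(np.arange(self.nx), np.arange(self.ny), indexing="ij")
        return self.h * np.hypot(ix - center[0], iy - center[1])
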