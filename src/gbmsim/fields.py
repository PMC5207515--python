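"""Spatial state of a simulation: cell-concentration fields on a 2D grid.

All concentrations are expressed as fractions of the initial live-brain
concentration (1.0).  The total concentration C is always derived from the
component fields, never integrated as an independent unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["StateFields"]


@dataclass
class StateFields:
    """Concentration fields of one model state.

    Single-cell model: glioma ``G``, live brain ``B``, necrotic debris ``N``.
    GoG model: proliferative ``P`` and invasive ``I`` glioma phenotypes
    replace ``G``.

    ``time`` is simulation time in hours.
    """

    B: np.ndarray
    N: np.ndarray
    G: Optional[np.ndarray] = None
    P: Optional[np.ndarray] = None
    I: Optional[np.ndarray] = None
    time: float = 0.0

    def __post_init__(self) -> None:
        if (self.G is None) == (self.P is None or self.I is None):
            raise ValueError("provide either G (single-cell) or both P and I (GoG)")
        for name, arr in self._arrays():
            if arr.shape != self.B.shape:
                raise ValueError(f"field {name} shape {arr.shape} != B shape {self.B.shape}")

    def _arrays(self):
        for name in ("G", "P", "I", "B", "N"):
            arr = getattr(self, name)
            if arr is not None:
                yield name, arr

    @property
    def is_gog(self) -> bool:
        return self.G is None

    @property
    def tumor(self) -> np.ndarray:
        """Total tumor-cell concentration (G, or P+I)."""
        return self.G if self.G is not None else self.P + self.I

    @property
    def C(self) -> np.ndarray:
        """Total cell concentration, recomputed from the components."""
        return self.tumor + self.B + self.N

    @property
    def shape(self) -> tuple:
        return self.B.shape

    def copy(self) -> "StateFields":
        return StateFields(
            B=self.B.copy(), N=self.N.copy(),
            G=None if self.G is None else self.G.copy(),
            P=None if self.P is None else self.P.copy(),
            I=None if self.I is None else self.I.copy(),
            time=self.time)

    def validate(self) -> None:
        """Raise if any field is negative or non-finite."""
        for name, arr in self._arrays():
            if not np.all(np.isfinite(arr)):
                raise FloatingPointError(f"field {name} contains non-finite values at t={self.time}")
            if np.any(arr < 0):
                raise ValueError(f"field {name} has negative values at t={self.time}")
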