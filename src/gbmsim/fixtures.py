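"""Synthetic field-state fixtures.

Deterministic constructed states used by the test suite and by examples:
no external data is ever needed.  Each fixture has a known ground truth
(e.g. the necrotic annulus has an exactly countable radiological-necrosis
core).
"""

from __future__ import annotations

import numpy as np

from .fields import StateFields
from .grid import Grid

__all__ = ["make_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("healthy", "gaussian_seed", "necrotic_annulus", "linear_B_ramp")


def make_fixture(kind: str, grid: Grid, seed: int = 0) -> StateFields:
    """Build a named synthetic state on ``grid``; deterministic given ``seed``.

    * ``healthy`` — pristine brain: G=0, B=1, N=0.
    * ``gaussian_seed`` — small Gaussian tumor (amplitude jittered
      reproducibly by ``seed``) on healthy brain.
    * ``necrotic_annulus`` — a dead core (B=0.05 < 0.30) of radius 1/8 of
      the domain, an annulus of glioma at the rim, healthy outside; the
      core's pixel count is the ground truth for necrosis-area tests.
    * ``linear_B_ramp`` — B increasing linearly along x with a central
      glioma blob; ground truth for advection-direction tests.
    """
    rng = np.random.default_rng(seed)
    B = np.ones(grid.shape)
    N = np.zeros(grid.shape)
    G = np.zeros(grid.shape)
    r = grid.radius_mm()

    if kind == "healthy":
        pass
    elif kind == "gaussian_seed":
        amp = 0.1 * (1.0 + 0.05 * rng.standard_normal())
        s = 2.0 * grid.h
        G = amp * np.exp(-r ** 2 / (2 * s ** 2))
        G[r > 3 * s] = 0.0
    elif kind == "necrotic_annulus":
        r_core = min(grid.extent_mm) / 8.0
        core = r < r_core
        rim = (r >= r_core) & (r < r_core + 2 * grid.h)
        B = np.where(core, 0.05, 1.0)
        N = np.where(core, 1.25, 0.0)   # debris left by dead brain + tumor
        G = np.where(rim, 0.2, 0.0)
    elif kind == "linear_B_ramp":
        x = np.arange(grid.nx, dtype=float)[:, None] * np.ones((1, grid.ny))
        B = 0.5 + 0.5 * x / max(grid.nx - 1, 1)
        s = 2.0 * grid.h
        G = 0.1 * np.exp(-r ** 2 / (2 * s ** 2))
        G[r > 3 * s] = 0.0
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; expected one of {FIXTURE_KINDS}")
    return StateFields(B=B, N=N, G=G)
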