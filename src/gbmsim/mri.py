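"""Virtual-MRI readouts: threshold masks and area fractions.

The simulation is read out the way a neuroradiologist would read serial MRI:

* **FLAIR** hyperintensity — any pixel invaded by even a small tumor burden,
  total concentration C > 1.003 (tumor cells exceed 0.3% of the initial
  brain concentration).
* **Vascular proliferation** (gadolinium enhancement) — C > C_vas = 1.12,
  a cell density only reachable through angiogenesis, which disrupts the
  blood-brain barrier.
* **Radiological necrosis** — live brain B < 0.30 (70% or more of the brain
  cells in the pixel are dead; visible on MRI).
* **Pathological necrosis** — B < 0.9995 (0.05% or more dead; visible only
  under the microscope).

Since 1.12 > 1.003 the enhancement mask is nested in the FLAIR mask, and
radiological necrosis is nested in pathological necrosis; both nestings are
enforced as invariants in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .fields import StateFields
from .grid import Grid

__all__ = [
    "RadiologyThresholds", "RadiologySnapshot", "compute_masks",
    "area_fraction", "render_panels", "SERIES_COLUMNS",
]

#: Column order of the area-fraction time series (CSV contract).
SERIES_COLUMNS = ["time_hr", "flair_pct", "vasc_pct",
                  "rad_necrosis_pct", "path_necrosis_pct", "max_C"]


@dataclass(frozen=True)
class RadiologyThresholds:
    """Concentration thresholds defining the four radiological readouts."""

    flair_C: float = 1.003
    vasc_C: float = 1.12
    rad_necrosis_B: float = 0.30
    path_necrosis_B: float = 0.9995

    def __post_init__(self) -> None:
        if not (self.flair_C < self.vasc_C):
            raise ValueError("FLAIR threshold must lie below the enhancement threshold")
        if not (self.rad_necrosis_B < self.path_necrosis_B):
            raise ValueError("radiological-necrosis B threshold must lie below pathological")


@dataclass
class RadiologySnapshot:
    """Masks and area fractions of one time point."""

    time: float
    flair: np.ndarray
    vasc: np.ndarray
    rad_necrosis: np.ndarray
    path_necrosis: np.ndarray
    flair_pct: float
    vasc_pct: float
    rad_necrosis_pct: float
    path_necrosis_pct: float
    max_C: float

    def row(self) -> Dict[str, float]:
        """One row of the area-fraction time series."""
        return {
            "time_hr": self.time,
            "flair_pct": self.flair_pct,
            "vasc_pct": self.vasc_pct,
            "rad_necrosis_pct": self.rad_necrosis_pct,
            "path_necrosis_pct": self.path_necrosis_pct,
            "max_C": self.max_C,
        }


def area_fraction(mask: np.ndarray, grid: Grid) -> float:
    """Percent of the brain domain covered by a boolean mask."""
    if mask.shape != grid.shape:
        raise ValueError(f"mask shape {mask.shape} does not match grid {grid.shape}")
    if grid.n_pixels == 0:
        raise ValueError("empty grid")
    return 100.0 * float(np.count_nonzero(mask)) / grid.n_pixels


def compute_masks(state: StateFields, grid: Grid,
                  thresholds: RadiologyThresholds | None = None) -> RadiologySnapshot:
    """Threshold a state into the four radiological masks (strict inequalities)."""
    th = thresholds or RadiologyThresholds()
    C = state.C
    B = state.B
    flair = C > th.flair_C
    vasc = C > th.vasc_C
    rad = B < th.rad_necrosis_B
    path = B < th.path_necrosis_B
    return RadiologySnapshot(
        time=state.time,
        flair=flair, vasc=vasc, rad_necrosis=rad, path_necrosis=path,
        flair_pct=area_fraction(flair, grid),
        vasc_pct=area_fraction(vasc, grid),
        rad_necrosis_pct=area_fraction(rad, grid),
        path_necrosis_pct=area_fraction(path, grid),
        max_C=float(C.max()),
    )


def render_panels(trajectory, times: Sequence[float], path_prefix: str,
                  thresholds: RadiologyThresholds | None = None) -> list:
    """Render composite virtual-MRI panels at the requested times.

    Layers (back to front): brain background, FLAIR halo (green),
    enhancement / vascular proliferation (orange), radiological necrosis
    (dark).  For each requested time the nearest stored state is used (a
    warning is emitted if no exact match exists).  Returns the written
    file paths.
    """
    import warnings

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    if not trajectory.states:
        raise ValueError("trajectory stores no states to render")
    stored = sorted(trajectory.states)
    written = []
    cmap = ListedColormap(["#d9d2c9", "#74c476", "#fd8d3c", "#3f3f3f"])
    for t in times:
        nearest = min(stored, key=lambda s: abs(s - t))
        if abs(nearest - t) > 1e-9:
            warnings.warn(f"no snapshot at t={t} hr; rendering nearest t={nearest} hr")
        snap = compute_masks(trajectory.states[nearest], trajectory.grid, thresholds)
        layer = np.zeros(snap.flair.shape, dtype=np.uint8)
        layer[snap.flair] = 1
        layer[snap.vasc] = 2
        layer[snap.rad_necrosis] = 3
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.imshow(layer.T, origin="lower", cmap=cmap, vmin=0, vmax=3,
                  interpolation="nearest")
        ax.set_title(f"t = {nearest / 730.0:.1f} mo")
        ax.set_axis_off()
        out = f"{path_prefix}_t{int(round(nearest)):06d}hr.png"
        fig.savefig(out, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(out)
    return written
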