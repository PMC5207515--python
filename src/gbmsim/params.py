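"""Model parameters for the single-glioma-cell and Go-or-Grow (GoG) tumor models.

Both models describe glioblastoma growth at MRI scale through four (or five)
interacting concentration fields on a homogeneous brain domain.  The kinetic
constants below control proliferation, necrosis and angiogenesis; the two
motility constants (``delta``, ``eta``) control passive diffusion and
hypoxia-driven bulk transport.  Defaults are the published reference values
for each model variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Optional

__all__ = ["ModelParams", "SINGLE_CELL_DEFAULTS", "GOG_DEFAULTS", "PARAM_RANGES"]

#: Published ranges for the motility parameters (single-cell model), used by
#: config validation to warn when a user override leaves the studied regime.
PARAM_RANGES = {
    "delta": (0.0, 1.0e-3),      # mm^2/hr, concentration-driven diffusion
    "eta": (1.4e-4, 1.4e-3),     # mm/hr, hypoxia-driven active transport
}

SINGLE_CELL_DEFAULTS = dict(tau=0.25, gamma=0.1, sigma=0.8, omega=1.1)
GOG_DEFAULTS = dict(tau=0.35, gamma=0.085, sigma=1.5, omega=1.1,
                    alpha=1.01, beta=1.0, phi=0.1)


@dataclass(frozen=True)
class ModelParams:
    """Rate constants and thresholds of the tumor kinetics.

    Parameters
    ----------
    model_kind:
        ``"single_cell"`` (one glioma phenotype G that both moves and divides)
        or ``"gog"`` (proliferative P and invasive I phenotypes that switch
        under hypoxia/normoxia; only I moves, only P divides).
    delta:
        Passive (concentration-driven) diffusion rate, mm^2/hr.
    eta:
        Hypoxia-driven active-transport rate, mm/hr.  Cells drift up the
        live-brain gradient, away from necrosis.
    tau:
        Maximal mitotic rate, 1/hr.
    gamma:
        Necrotic rate constant, 1/hr.
    sigma:
        Angiogenic rate: the death threshold is lifted by
        ``sigma * log(1 + G)`` above its initial value, modelling
        neovascularization.  ``sigma = 0`` models anti-angiogenic
        (bevacizumab) therapy.
    omega:
        Initial necrotic threshold (total-concentration units).  1.1 means
        the brain sustains a tumor burden of 10% of the initial brain
        concentration before cells start dying.
    alpha, beta:
        GoG only: P->I conversion rate under hypoxia and I->P conversion
        rate under normoxia, 1/hr.
    phi:
        GoG only: fixed gap ``C_ltm - C_hyp`` between the death and hypoxia
        thresholds.
    switch_steepness:
        Slope constant k of the tanh switch functions; 100 makes the
        mitosis/necrosis transition about 0.01 concentration units wide.
    necrosis_rate_max:
        Numerical-safety cap on the necrotic rate (1/hr).  Must never bind
        in default-parameter runs.
    """

    model_kind: str = "single_cell"
    delta: float = 1.0e-3
    eta: float = 1.4e-3
    tau: float = 0.25
    gamma: float = 0.1
    sigma: float = 0.8
    omega: float = 1.1
    alpha: Optional[float] = None
    beta: Optional[float] = None
    phi: Optional[float] = None
    switch_steepness: float = 100.0
    necrosis_rate_max: float = 50.0

    def __post_init__(self) -> None:
        if self.model_kind not in ("single_cell", "gog"):
            raise ValueError(f"unknown model_kind: {self.model_kind!r}")
        for name in ("delta", "eta", "tau", "gamma", "sigma"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be a finite non-negative rate, got {v}")
        if self.omega < 1.0:
            raise ValueError(
                f"omega must be >= 1.0 (the initial brain concentration), got {self.omega}")
        if self.switch_steepness <= 0:
            raise ValueError("switch_steepness must be positive")
        if self.model_kind == "gog":
            missing = [n for n in ("alpha", "beta", "phi") if getattr(self, n) is None]
            if missing:
                raise ValueError(f"gog model requires {', '.join(missing)}")
            for name in ("alpha", "beta", "phi"):
                if getattr(self, name) < 0:
                    raise ValueError(f"{name} must be non-negative")

    @property
    def is_gog(self) -> bool:
        return self.model_kind == "gog"

    @classmethod
    def single_cell(cls, **overrides) -> "ModelParams":
        """Single-cell model with reference kinetic defaults."""
        kw = dict(SINGLE_CELL_DEFAULTS)
        kw.update(overrides)
        return cls(model_kind="single_cell", **kw)

    @classmethod
    def gog(cls, **overrides) -> "ModelParams":
        """Two-cell Go-or-Grow model with reference kinetic defaults."""
        kw = dict(GOG_DEFAULTS)
        kw.update(overrides)
        return cls(model_kind="gog", **kw)

    def with_sigma(self, sigma: float) -> "ModelParams":
        """Copy with a new angiogenic rate (``0`` = anti-angiogenic therapy)."""
        return replace(self, sigma=sigma)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
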