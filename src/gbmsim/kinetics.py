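"""Local (per-grid-cell) kinetics of the tumor models.

Everything here is pointwise: the tanh switch functions that gate mitosis
and necrosis, the angiogenesis-lifted death threshold, and the full reaction
right-hand sides of both models with the two spatial transport terms
excluded.  The spatial solver composes these with diffusion and active
transport.

Model summary (single-cell)
---------------------------
The death threshold is ``C_ltm = sigma*log(1+G) + omega``: angiogenesis
(sigma > 0) lets a growing tumor raise the local carrying capacity
logarithmically.  Below C_ltm glioma cells divide at rate ``tau``; above it
mitosis shuts off and all live cells convert to necrotic debris at rate
``gamma*(1+G)/(B+0.01)``, which accelerates as the live brain dies out.
The switches are smooth, ``(1 +/- tanh(k*(C_ltm - C)))/2`` with k = 100.
"""

from __future__ import annotations

from typing import Dict, Tuple, Union

import numpy as np

from .fields import StateFields
from .params import ModelParams

__all__ = [
    "switch_below", "switch_above", "necrotic_threshold", "mitotic_rate",
    "necrosis_rate", "hypoxia_measure", "reaction_terms", "reaction_rhs_flat",
]

ArrayLike = Union[float, np.ndarray]

#: Regularizer in the necrosis-rate denominator, as published.
B_REGULARIZER = 0.01


def switch_below(C: ArrayLike, thresh: ArrayLike, k: float) -> ArrayLike:
    """Smooth indicator that C is below a threshold.

    ``(1 + tanh(k*(thresh - C)))/2``: ~1 well below the threshold, 1/2 at
    it, ~0 well above.  Gates mitosis.
    """
    if k <= 0:
        raise ValueError("switch steepness k must be positive")
    return 0.5 * (1.0 + np.tanh(k * (np.asarray(thresh) - C)))


def switch_above(C: ArrayLike, thresh: ArrayLike, k: float) -> ArrayLike:
    """Complement of :func:`switch_below`; gates necrosis and hypoxia."""
    if k <= 0:
        raise ValueError("switch steepness k must be positive")
    return 0.5 * (1.0 - np.tanh(k * (np.asarray(thresh) - C)))


def necrotic_threshold(G_like: ArrayLike, params: ModelParams) -> ArrayLike:
    """Death threshold C_ltm lifted by angiogenesis.

    Single-cell: ``C_ltm = sigma*log(1+G) + omega`` (natural log).
    GoG: the hypoxic threshold is ``C_hyp = sigma*log(1+P) + omega`` and
    ``C_ltm = C_hyp + phi``.

    Parameters
    ----------
    G_like:
        Glioma concentration G (single-cell) or P (GoG); must be >= 0.
    """
    G_like = np.asarray(G_like, dtype=float)
    if np.any(G_like < 0):
        raise ValueError("negative glioma concentration")
    chyp = params.sigma * np.log1p(G_like) + params.omega
    if params.is_gog:
        return chyp + params.phi
    return chyp


def hypoxic_threshold(P: ArrayLike, params: ModelParams) -> ArrayLike:
    """C_hyp for the GoG model (phenotype-switch threshold)."""
    if not params.is_gog:
        raise ValueError("hypoxic threshold is defined for the GoG model only")
    P = np.asarray(P, dtype=float)
    if np.any(P < 0):
        raise ValueError("negative glioma concentration")
    return params.sigma * np.log1p(P) + params.omega


def mitotic_rate(C: ArrayLike, C_thresh: ArrayLike, params: ModelParams) -> ArrayLike:
    """Mitotic rate M in 1/hr: full rate tau below the threshold, ~0 above.

    The gating threshold is C_ltm for the single-cell model and C_hyp for
    the GoG model (where mitosis stops already at the onset of hypoxia).
    """
    return params.tau * switch_below(C, C_thresh, params.switch_steepness)


def necrosis_rate(G_total: ArrayLike, B: ArrayLike, C: ArrayLike,
                  C_ltm: ArrayLike, params: ModelParams) -> ArrayLike:
    """Necrotic rate gamma*F in 1/hr, applied identically to all live fields.

    ``gamma * (1 + G_total)/(B + 0.01) * switch_above(C, C_ltm)`` where
    G_total is G (single-cell) or P+I (GoG).  The rate blows up as the live
    brain vanishes; a numerical-safety cap ``necrosis_rate_max`` bounds it
    (never binding with default parameters).
    """
    B = np.asarray(B, dtype=float)
    G_total = np.asarray(G_total, dtype=float)
    if np.any(B < 0) or np.any(G_total < 0):
        raise ValueError("negative concentration")
    rate = (params.gamma * (1.0 + G_total) / (B + B_REGULARIZER)
            * switch_above(C, C_ltm, params.switch_steepness))
    return np.minimum(rate, params.necrosis_rate_max)


def hypoxia_measure(C: ArrayLike, C_hyp: ArrayLike, params: ModelParams) -> ArrayLike:
    """GoG hypoxia measure H in [0, 1]: ~0 in normoxia, ~1 in hypoxia.

    Complementary to the GoG mitotic switch at the same threshold, so a
    grid cell is never simultaneously fully proliferative and fully
    hypoxic.
    """
    if not params.is_gog:
        raise ValueError("hypoxia measure is defined for the GoG model only")
    return switch_above(C, C_hyp, params.switch_steepness)


def local_rates(state: StateFields, params: ModelParams) -> Dict[str, np.ndarray]:
    """All pointwise rates needed by the reaction update.

    Returns M (mitosis), gF (necrosis) and, for GoG, the conversion rates
    a = alpha*H (P->I) and b = beta*(1-H) (I->P).
    """
    C = state.C
    if params.is_gog:
        chyp = hypoxic_threshold(state.P, params)
        cltm = chyp + params.phi
        H = hypoxia_measure(C, chyp, params)
        return {
            "M": mitotic_rate(C, chyp, params),
            "gF": necrosis_rate(state.P + state.I, state.B, C, cltm, params),
            "a": params.alpha * H,
            "b": params.beta * (1.0 - H),
        }
    cltm = necrotic_threshold(state.G, params)
    return {
        "M": mitotic_rate(C, cltm, params),
        "gF": necrosis_rate(state.G, state.B, C, cltm, params),
    }


def reaction_terms(state: StateFields, params: ModelParams) -> Dict[str, np.ndarray]:
    """Per-field time derivatives of the reaction kinetics (transport excluded).

    Single-cell::

        dG = M*G - gF*G      dB = -gF*B      dN = gF*(B + G)

    GoG::

        dP = M*P - a*P + b*I - gF*P
        dI = a*P - b*I - gF*I
        dB = -gF*B
        dN = gF*(B + P + I)

    Necrosis conserves mass exactly (the derivatives sum to M*G, resp. M*P:
    mitosis is the only source).
    """
    state.validate()
    r = local_rates(state, params)
    M, gF = r["M"], r["gF"]
    if params.is_gog:
        conv = r["a"] * state.P - r["b"] * state.I
        return {
            "P": M * state.P - conv - gF * state.P,
            "I": conv - gF * state.I,
            "B": -gF * state.B,
            "N": gF * (state.B + state.P + state.I),
        }
    return {
        "G": M * state.G - gF * state.G,
        "B": -gF * state.B,
        "N": gF * (state.B + state.G),
    }


def reaction_rhs_flat(t: float, y: np.ndarray, params: ModelParams) -> np.ndarray:
    """Reaction right-hand side in flat-vector form for ODE integrators.

    Layout: ``[G, B, N]`` (single-cell) or ``[P, I, B, N]`` (GoG), each a
    scalar or flattened field of equal length.  Used by the per-pixel ODE
    oracle tests and valid for any adaptive integrator.
    """
    y = np.asarray(y, dtype=float)
    n = y.size // (4 if params.is_gog else 3)
    shape = (n,)
    if params.is_gog:
        P, I, B, N = (y[i * n:(i + 1) * n].reshape(shape) for i in range(4))
        state = StateFields(B=np.maximum(B, 0), N=np.maximum(N, 0),
                            P=np.maximum(P, 0), I=np.maximum(I, 0), time=t)
        d = reaction_terms(state, params)
        return np.concatenate([d["P"], d["I"], d["B"], d["N"]])
    G, B, N = (y[i * n:(i + 1) * n].reshape(shape) for i in range(3))
    state = StateFields(B=np.maximum(B, 0), N=np.maximum(N, 0),
                        G=np.maximum(G, 0), time=t)
    d = reaction_terms(state, params)
    return np.concatenate([d["G"], d["B"], d["N"]])
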