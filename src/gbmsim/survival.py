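"""Survival analysis for the simulated trials.

Self-contained product-limit (Kaplan-Meier) estimator and two-sample
Mantel-Haenszel log-rank test — small enough to own outright, and owning
them keeps the conventions explicit:

* deaths tied at one time use the hypergeometric variance with d_j > 1;
* a censoring tied with a death at the same time counts the death first
  (the censored subject is still at risk at that time);
* the median is the smallest time t with S(t) <= 0.5 (``nan`` if the curve
  never reaches 0.5 — reported as "not reached").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import special

__all__ = ["SurvivalSample", "KaplanMeierFit", "kaplan_meier", "logrank"]


@dataclass(frozen=True)
class SurvivalSample:
    """Event times with censoring flags (1 = death observed, 0 = censored)."""

    times: np.ndarray
    events: np.ndarray
    label: str = ""

    def __init__(self, times: Sequence[float], events: Sequence[int] | None = None,
                 label: str = "") -> None:
        t = np.asarray(times, dtype=float)
        e = (np.ones_like(t, dtype=int) if events is None
             else np.asarray(events, dtype=int))
        if t.size == 0:
            raise ValueError("empty survival sample")
        if t.shape != e.shape:
            raise ValueError("times and events must have equal length")
        if np.any(t < 0):
            raise ValueError("negative survival time")
        if not np.all(np.isin(e, (0, 1))):
            raise ValueError("event flags must be 0 or 1")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", e)
        object.__setattr__(self, "label", label)

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def n_events(self) -> int:
        return int(self.events.sum())


@dataclass
class KaplanMeierFit:
    """Product-limit estimate: step function S(t) and its median."""

    event_times: np.ndarray   # distinct death times, ascending
    survival: np.ndarray      # S(t) just after each death time
    at_risk: np.ndarray
    deaths: np.ndarray
    median: float             # nan = not reached

    def survival_at(self, t) -> np.ndarray:
        """Right-continuous S(t)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right")
        s = np.concatenate([[1.0], self.survival])
        return s[idx]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.event_times,
            "at_risk": self.at_risk,
            "deaths": self.deaths,
            "survival": self.survival,
        })


def _risk_table(sample: SurvivalSample) -> pd.DataFrame:
    """Distinct death times with at-risk and death counts.

    Subjects censored exactly at a death time are counted as still at risk
    at that time (death first convention).
    """
    t, e = sample.times, sample.events
    death_times = np.unique(t[e == 1])
    n_at_risk = np.array([(t >= dt).sum() for dt in death_times])
    d = np.array([((t == dt) & (e == 1)).sum() for dt in death_times])
    return pd.DataFrame({"time": death_times, "n": n_at_risk, "d": d})


def kaplan_meier(sample: SurvivalSample) -> KaplanMeierFit:
    """Product-limit estimator S(t) = prod_{t_j <= t} (1 - d_j / n_j)."""
    tab = _risk_table(sample)
    factors = 1.0 - tab["d"].to_numpy() / tab["n"].to_numpy()
    surv = np.cumprod(factors) if len(tab) else np.array([])
    below = np.nonzero(surv <= 0.5 + 1e-15)[0]
    median = float(tab["time"].iloc[below[0]]) if below.size else float("nan")
    return KaplanMeierFit(
        event_times=tab["time"].to_numpy(),
        survival=surv,
        at_risk=tab["n"].to_numpy(),
        deaths=tab["d"].to_numpy(),
        median=median,
    )


def logrank(sample_a: SurvivalSample, sample_b: SurvivalSample) -> Tuple[float, float]:
    """Two-sample Mantel-Haenszel log-rank test.

    At each distinct death time ``j`` (pooled), with ``n_j`` at risk
    (``n_aj`` in group A), ``d_j`` total deaths and ``d_aj`` deaths in A,
    the observed-minus-expected contribution is ``d_aj - d_j n_aj / n_j``
    with hypergeometric variance
    ``d_j (n_aj/n_j) (1 - n_aj/n_j) (n_j - d_j)/(n_j - 1)``.
    Returns ``(chi2, p)`` with the p-value from the chi-square(1) upper
    tail; symmetric in group order.
    """
    if sample_a.n_events == 0 or sample_b.n_events == 0:
        raise ValueError("log-rank requires at least one event in each group")
    ta, ea = sample_a.times, sample_a.events
    tb, eb = sample_b.times, sample_b.events
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    death_times = np.unique(t[e == 1])
    O_minus_E = 0.0
    V = 0.0
    for dt in death_times:
        n_a = float((ta >= dt).sum())
        n_b = float((tb >= dt).sum())
        n = n_a + n_b
        d_a = float(((ta == dt) & (ea == 1)).sum())
        d = d_a + float(((tb == dt) & (eb == 1)).sum())
        if n < 2:
            continue
        O_minus_E += d_a - d * n_a / n
        V += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    if V == 0:
        return 0.0, 1.0
    chi2 = O_minus_E ** 2 / V
    # chi-square(1) survival function via the complementary error function
    p = float(special.erfc(np.sqrt(chi2 / 2.0)))
    return float(chi2), p
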