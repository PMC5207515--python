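"""In-silico anti-angiogenic (bevacizumab) clinical trial.

A virtual patient is one PDE simulation watched through its virtual-MRI
area fractions.  *Diagnosis* fires when the vascular-proliferation area
(or, for hypoxia-driven tumors, radiological-necrosis area) first reaches a
critical percent of the brain; treated patients then have the angiogenic
rate sigma set to zero — the model's reading of bevacizumab, which
collapses the death threshold back toward its avascular value.  *Death*
fires when the first of the arm's death readouts reaches its critical
percent.  Overall survival is death time minus diagnosis time.

The default protocol runs four groups:

========================  =======================  =========================
group                     diagnosis titrations      death titrations
========================  =======================  =========================
PP1 highly dispersive     %VP {1, 1.5, 2, 2.5, 3}  %FLAIR {62..66}
PP2 moderately dispersive %VP {1, 1.5, 2, 2.5, 3}  %rad.necrosis {3.4..4.8}
PP3 hypoxia driven        %VP or %nec (paired)     %rad.necrosis {3.4..4.8}
untreated controls        as the matching arm      %VP {15..23} / %nec
========================  =======================  =========================

Five diagnosis x five death titrations give 25 patients per treated arm and
75 pooled untreated controls.  All patients sharing a motility preset share
the pre-diagnosis trajectory: one base run per preset, with treated
branches forked from the stored diagnosis-time states.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fields import StateFields
from .grid import Grid
from .params import ModelParams
from .solver import SeedSpec, SimulationConfig, Trajectory, simulate
from .survival import SurvivalSample, kaplan_meier, logrank

__all__ = [
    "HOURS_PER_MONTH", "MOTILITY_PRESETS", "MotilityPreset", "EventCriterion",
    "TrialArm", "PatientRecord", "TrialResult", "default_arms",
    "detect_event", "run_patient", "run_arm", "run_trial",
    "classify_progression",
]

#: Reporting-layer conversion; simulation time is always hours.
HOURS_PER_MONTH = 730.0

READOUTS = ("vasc_pct", "flair_pct", "rad_necrosis_pct")


@dataclass(frozen=True)
class MotilityPreset:
    """One motility phenotype: diffusion and active-transport magnitudes."""

    name: str
    delta: float   # mm^2/hr, concentration-driven
    eta: float     # mm/hr, hypoxia-driven

    def apply(self, params: ModelParams) -> ModelParams:
        return replace(params, delta=self.delta, eta=self.eta)


#: Calibrated motility phenotypes.  The published model gives only the
#: admissible ranges (delta in [0, 1e-3] mm^2/hr, eta in [1.4e-4, 1.4e-3]
#: mm/hr) and qualitative High/Moderate/Low labels; these values were fixed
#: by the `calibrate` sweep against the reference median survivals on the
#: default 120x120 grid and stay strictly inside the ranges.  Only the
#: relative ordering of delta across phenotypes is meaningful at this grid
#: resolution (see the methods note on desk-scale front speeds).
MOTILITY_PRESETS: Dict[str, MotilityPreset] = {
    "high": MotilityPreset("high", delta=1.0e-4, eta=1.4e-4),
    "moderate": MotilityPreset("moderate", delta=1.0e-5, eta=1.4e-4),
    "low": MotilityPreset("low", delta=1.0e-8, eta=1.4e-4),
}


@dataclass(frozen=True)
class EventCriterion:
    """A threshold on one area readout, firing when readout >= threshold %."""

    readout: str
    threshold: float
    role: str = "diagnosis"

    def __post_init__(self) -> None:
        if self.readout not in READOUTS:
            raise ValueError(f"unknown readout {self.readout!r}; expected one of {READOUTS}")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")

    def describe(self) -> str:
        return f"{self.readout}>={self.threshold:g}%"


CriterionSet = Tuple[EventCriterion, ...]   # OR-set: first to fire wins


@dataclass(frozen=True)
class TrialArm:
    """One protocol row: a motility preset plus titration grids."""

    name: str
    preset: str
    diagnosis: Tuple[CriterionSet, ...]
    death: Tuple[CriterionSet, ...]
    treated: bool
    group: str

    def __post_init__(self) -> None:
        if len(self.diagnosis) == 0 or len(self.death) == 0:
            raise ValueError("arm needs at least one diagnosis and one death titration")


@dataclass
class PatientRecord:
    """One simulated patient."""

    arm: str
    group: str
    preset: str
    diagnosis_criterion: str
    diagnosis_time_hr: float
    death_criterion: str
    death_time_hr: float
    survival_months: float
    censored: bool = False

    def row(self) -> dict:
        return {
            "arm": self.arm, "group": self.group, "preset": self.preset,
            "diagnosis_criterion": self.diagnosis_criterion,
            "diagnosis_time_hr": self.diagnosis_time_hr,
            "death_criterion": self.death_criterion,
            "death_time_hr": self.death_time_hr,
            "survival_months": self.survival_months,
            "censored": int(self.censored),
        }


@dataclass
class TrialResult:
    """All patient records plus survival summaries."""

    records: pd.DataFrame
    samples: Dict[str, SurvivalSample]
    medians: Dict[str, float]
    logrank_tests: Dict[Tuple[str, str], Tuple[float, float]]
    progression: Dict[str, str] = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "group_sizes": {g: int(s.n) for g, s in self.samples.items()},
            "median_survival_months": self.medians,
            "logrank": {f"{a} vs {b}": {"chi2": c, "p": p}
                        for (a, b), (c, p) in self.logrank_tests.items()},
            "progression_patterns": self.progression,
        }


def _vp(th: float) -> EventCriterion:
    return EventCriterion("vasc_pct", th)


def _nec(th: float, role: str = "death") -> EventCriterion:
    return EventCriterion("rad_necrosis_pct", th, role)


def default_arms() -> List[TrialArm]:
    """The default protocol: three treated arms plus matched untreated rows."""
    vp_diag = [1.0, 1.5, 2.0, 2.5, 3.0]
    nec_diag = [0.5, 0.75, 1.0, 1.25, 1.5]
    flair_death = [62.0, 63.0, 64.0, 65.0, 66.0]
    nec_death = [3.4, 3.8, 4.2, 4.6, 4.8]
    vp_death = [15.0, 17.0, 19.0, 21.0, 23.0]

    vp_only = tuple((_vp(v),) for v in vp_diag)
    # hypoxia-driven arm: i-th VP titration paired with i-th necrosis titration
    paired = tuple((_vp(v), _nec(n, "diagnosis"))
                   for v, n in zip(vp_diag, nec_diag))
    return [
        TrialArm("PP1_highly_dispersive", "high", vp_only,
                 tuple((EventCriterion("flair_pct", f, "death"),) for f in flair_death),
                 treated=True, group="PP1"),
        TrialArm("PP2_moderately_dispersive", "moderate", vp_only,
                 tuple((_nec(n),) for n in nec_death), treated=True, group="PP2"),
        TrialArm("PP3_hypoxia_driven", "low", paired,
                 tuple((_nec(n),) for n in nec_death), treated=True, group="PP3"),
        TrialArm("control_high", "high", vp_only,
                 tuple((_vp(v),) for v in vp_death), treated=False, group="untreated"),
        TrialArm("control_moderate", "moderate", vp_only,
                 tuple((_vp(v),) for v in vp_death), treated=False, group="untreated"),
        TrialArm("control_low", "low", paired,
                 tuple((_nec(n),) for n in nec_death), treated=False, group="untreated"),
    ]


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------

def _first_crossing(series: pd.DataFrame, criterion: EventCriterion,
                    t_min: float = -np.inf) -> Optional[float]:
    """Earliest time the readout reaches the threshold, linearly interpolated."""
    t = series["time_hr"].to_numpy()
    y = series[criterion.readout].to_numpy()
    keep = t >= t_min - 1e-9
    t, y = t[keep], y[keep]
    hit = np.nonzero(y >= criterion.threshold)[0]
    if hit.size == 0:
        return None
    i = int(hit[0])
    if i == 0 or y[i] == y[i - 1]:
        return float(t[i])
    frac = (criterion.threshold - y[i - 1]) / (y[i] - y[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def detect_event(series: pd.DataFrame, criteria: Sequence[EventCriterion],
                 t_min: float = -np.inf) -> Optional[Tuple[float, EventCriterion]]:
    """First firing among an OR-set of criteria, or None if none fires."""
    best: Optional[Tuple[float, EventCriterion]] = None
    for c in criteria:
        tc = _first_crossing(series, c, t_min)
        if tc is not None and (best is None or tc < best[0]):
            best = (tc, c)
    return best


# ---------------------------------------------------------------------------
# patient and arm runners
# ---------------------------------------------------------------------------

class _CrossingWatcher:
    """Stops a simulation once every watched OR-set has fired.

    Stores the interpolated firing time and criterion per set and, on
    request, a copy of the state at the first snapshot past each firing
    (used to fork treated branches).
    """

    def __init__(self, criterion_sets: Sequence[CriterionSet],
                 keep_states: bool = False) -> None:
        self.sets = list(criterion_sets)
        self.pending = set(range(len(self.sets)))
        self.fired: Dict[int, Tuple[float, EventCriterion]] = {}
        self.states: Dict[int, StateFields] = {}
        self.keep_states = keep_states
        self._prev_row: Optional[dict] = None

    def __call__(self, state: StateFields, snap) -> bool:
        row = snap.row()
        prev = self._prev_row
        self._prev_row = row
        for i in sorted(self.pending):
            firing = None
            for c in self.sets[i]:
                y1 = row[c.readout]
                if y1 < c.threshold:
                    continue
                if prev is None or prev[c.readout] >= c.threshold or y1 == prev[c.readout]:
                    tc = row["time_hr"]
                else:
                    y0 = prev[c.readout]
                    frac = (c.threshold - y0) / (y1 - y0)
                    tc = prev["time_hr"] + frac * (row["time_hr"] - prev["time_hr"])
                if firing is None or tc < firing[0]:
                    firing = (tc, c)
            if firing is not None:
                self.fired[i] = firing
                self.pending.discard(i)
                if self.keep_states:
                    self.states[i] = state.copy()
        return not self.pending


def _preset(name_or_preset, presets: Optional[Dict[str, MotilityPreset]]) -> MotilityPreset:
    if isinstance(name_or_preset, MotilityPreset):
        return name_or_preset
    table = presets or MOTILITY_PRESETS
    return table[name_or_preset]


def _arm_config(arm_preset: MotilityPreset, base: SimulationConfig) -> SimulationConfig:
    return base.replace(params=arm_preset.apply(base.params))


def run_arm(arm: TrialArm, base: Optional[SimulationConfig] = None,
            presets: Optional[Dict[str, MotilityPreset]] = None,
            ) -> Tuple[List[PatientRecord], Dict[str, object]]:
    """Run every patient of one arm, sharing the pre-diagnosis trajectory.

    Returns the records plus diagnostics: the base trajectory, per-branch
    trajectories and the dominant progression pattern (treated arms).
    """
    base = base or SimulationConfig()
    preset = _preset(arm.preset, presets)
    cfg = _arm_config(preset, base)

    watch_diag = _CrossingWatcher(arm.diagnosis, keep_states=arm.treated)
    if arm.treated:
        base_traj = simulate(cfg, hooks=[watch_diag])
    else:
        watch_death = _CrossingWatcher(arm.death)

        def both_done(s, snap):
            diag_done = watch_diag(s, snap)
            death_done = watch_death(s, snap)
            return diag_done and death_done

        base_traj = simulate(cfg, hooks=[both_done])

    if watch_diag.pending:
        missing = sorted(watch_diag.pending)
        raise RuntimeError(
            f"arm {arm.name}: diagnosis titrations {missing} never fired "
            f"within t_max={cfg.t_max:g} hr")

    records: List[PatientRecord] = []
    diagnostics: Dict[str, object] = {"base": base_traj, "branches": {}}

    if not arm.treated:
        for i, (t_diag, c_diag) in sorted(watch_diag.fired.items()):
            for j, death_set in enumerate(arm.death):
                fired = watch_death.fired.get(j)
                records.append(_make_record(arm, preset, t_diag, c_diag, fired,
                                            t_end=base_traj.final_state.time))
        return records, diagnostics

    patterns = []
    for i, (t_diag, c_diag) in sorted(watch_diag.fired.items()):
        branch_state = watch_diag.states[i]
        branch_cfg = cfg.replace(params=cfg.params.with_sigma(0.0))
        watch_death = _CrossingWatcher(arm.death)
        branch = simulate(branch_cfg, start=branch_state, hooks=[watch_death])
        diagnostics["branches"][i] = branch
        diag_row = _row_at(base_traj, branch_state.time)
        patterns.append(classify_progression(branch, diag_row, cfg.grid))
        for j, death_set in enumerate(arm.death):
            fired = watch_death.fired.get(j)
            records.append(_make_record(arm, preset, t_diag, c_diag, fired,
                                        t_end=branch.final_state.time))
    diagnostics["progression"] = max(set(patterns), key=patterns.count)
    diagnostics["progression_per_branch"] = patterns
    return records, diagnostics


def _row_at(traj: Trajectory, time_hr: float) -> dict:
    rows = [s.row() for s in traj.snapshots]
    best = min(rows, key=lambda r: abs(r["time_hr"] - time_hr))
    return best


def _make_record(arm: TrialArm, preset: MotilityPreset, t_diag: float,
                 c_diag: EventCriterion,
                 fired: Optional[Tuple[float, EventCriterion]],
                 t_end: float) -> PatientRecord:
    if fired is None:
        t_death, desc, censored = t_end, "censored@t_max", True
    else:
        t_death, crit = fired
        desc, censored = crit.describe(), False
    t_death = max(t_death, t_diag)
    return PatientRecord(
        arm=arm.name, group=arm.group, preset=preset.name,
        diagnosis_criterion=c_diag.describe(), diagnosis_time_hr=t_diag,
        death_criterion=desc, death_time_hr=t_death,
        survival_months=(t_death - t_diag) / HOURS_PER_MONTH,
        censored=censored)


def run_patient(preset, diagnosis_criteria: Sequence[EventCriterion],
                death_criteria: Sequence[EventCriterion], treated: bool,
                base: Optional[SimulationConfig] = None,
                presets: Optional[Dict[str, MotilityPreset]] = None) -> PatientRecord:
    """Simulate a single patient (one diagnosis OR-set, one death OR-set)."""
    arm = TrialArm("single_patient", preset if isinstance(preset, str) else preset.name,
                   (tuple(diagnosis_criteria),), (tuple(death_criteria),),
                   treated=treated, group="single")
    table = dict(presets or MOTILITY_PRESETS)
    if isinstance(preset, MotilityPreset):
        table[preset.name] = preset
    records, _ = run_arm(arm, base, table)
    return records[0]


# ---------------------------------------------------------------------------
# progression-pattern classification
# ---------------------------------------------------------------------------

def classify_progression(branch: Trajectory, diagnosis_row: dict, grid: Grid,
                         flair_dominant_pct: float = 30.0,
                         rim_margin_mm: float = 2.5) -> str:
    """Classify a treated branch by what is expanding at the time of death.

    * ``PP1`` (expanding FLAIR): the tumor kills by brain-wide low-density
      invasion — the FLAIR burden at death is a large fraction of the brain
      (>= ``flair_dominant_pct``), far beyond any necrosis criterion.
    * ``PP2`` (expanding FLAIR + necrosis): necrosis expands to a lethal
      area while the FLAIR margin runs ahead of the necrotic rim by more
      than ``rim_margin_mm`` (equivalent-disk radii).
    * ``PP3`` (expanding necrosis): necrosis expands with the FLAIR margin
      hovering within ``rim_margin_mm`` of the rim.

    The margins are desk-scale operationalizations: on an MRI-resolution
    grid the low-density halo ahead of the necrotic rim is proportional to
    the invasion-front speed and spans only a few pixels, so the
    equivalent-disk radius difference sqrt(A_FLAIR/pi) - sqrt(A_nec/pi)
    (in mm) is the robust discriminant.
    """
    final = branch.snapshots[-1]
    if final.flair_pct >= flair_dominant_pct:
        return "PP1"
    a_dom = grid.n_pixels * grid.pixel_area
    r_f = math.sqrt(final.flair_pct / 100.0 * a_dom / math.pi)
    r_n = math.sqrt(final.rad_necrosis_pct / 100.0 * a_dom / math.pi)
    return "PP2" if r_f - r_n > rim_margin_mm else "PP3"


# ---------------------------------------------------------------------------
# the full trial
# ---------------------------------------------------------------------------

def run_trial(arms: Optional[Sequence[TrialArm]] = None,
              base: Optional[SimulationConfig] = None,
              presets: Optional[Dict[str, MotilityPreset]] = None,
              ) -> TrialResult:
    """Run the whole protocol and assemble the survival analysis.

    With default arms: 25 records per treated arm and 75 pooled untreated
    controls.  Per group: Kaplan-Meier median; across groups: all pairwise
    Mantel-Haenszel log-rank tests.  Deterministic given the configuration.
    """
    arms = list(arms) if arms is not None else default_arms()
    all_records: List[PatientRecord] = []
    progression: Dict[str, str] = {}
    for arm in arms:
        records, diag = run_arm(arm, base, presets)
        all_records.extend(records)
        if arm.treated and "progression" in diag:
            progression[arm.group] = diag["progression"]

    df = pd.DataFrame([r.row() for r in all_records])
    samples: Dict[str, SurvivalSample] = {}
    medians: Dict[str, float] = {}
    for group, sub in df.groupby("group", sort=False):
        sample = SurvivalSample(sub["survival_months"].to_numpy(),
                                1 - sub["censored"].to_numpy(), label=group)
        samples[group] = sample
        medians[group] = kaplan_meier(sample).median
    tests = {}
    for a, b in itertools.combinations(sorted(samples), 2):
        tests[(a, b)] = logrank(samples[a], samples[b])
    return TrialResult(records=df, samples=samples, medians=medians,
                       logrank_tests=tests, progression=progression)
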