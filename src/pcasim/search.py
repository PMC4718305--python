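"""Exhaustive search over step-down basal infusion schedules.

Reproduces the design step behind a model-based PCA program: enumerate
candidate basal schedules (an initial rate, a step-down time, a subsequent
rate) on top of a fixed loading dose and PCA settings, simulate each
deterministically *without* demand boluses, and select the schedule with
the least total scheduled drug among those that keep the reference
concentration inside the therapeutic window throughout a constraint
interval.

Demand boluses are excluded from the feasibility check on purpose: they can
only raise a linear system's concentrations, so a schedule feasible without
them stays feasible with them, and excluding them keeps the search
deterministic.

Ties on total dose are broken by lower peak concentration, then by
enumeration order (initial rate, step-down time, subsequent rate ascending).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .events import BolusEvent, DemandPolicy, InfusionSegment, PCAProgram, Regimen
from .metrics import WindowMetrics, window_metrics
from .pk_core import PKParameters, TherapeuticWindow
from .simulate import ConcentrationSeries, run

__all__ = ["SearchSpace", "CandidateResult", "SearchResult", "search", "step_down_regimen"]


@dataclass(frozen=True)
class SearchSpace:
    """Candidate grid for a two-phase (step-down) basal schedule.

    Every ordered pair of ``candidate_rates`` (μg/h) is tried as
    (initial rate, subsequent rate) around every step-down time; the
    loading events, demand dose and lockout are fixed across candidates.
    """

    candidate_rates: tuple[float, ...]
    step_down_times: tuple[float, ...]
    loading_events: tuple[BolusEvent | InfusionSegment, ...] = ()
    demand_dose: float = 10.0
    lockout: float = 15.0
    horizon: float = 2880.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "candidate_rates", tuple(self.candidate_rates))
        object.__setattr__(self, "step_down_times", tuple(self.step_down_times))
        object.__setattr__(self, "loading_events", tuple(self.loading_events))
        if not self.candidate_rates or not self.step_down_times:
            raise ValueError("search space must contain at least one rate and one step time")
        if any(r < 0 for r in self.candidate_rates):
            raise ValueError("candidate rates must be non-negative")
        if list(self.step_down_times) != sorted(self.step_down_times):
            raise ValueError("step_down_times must be increasing")


def step_down_regimen(
    space: SearchSpace, initial_rate: float, step_time: float, later_rate: float
) -> Regimen:
    """Candidate regimen: loading events + two-phase basal, no demands."""
    basal = []
    if initial_rate > 0:
        basal.append(InfusionSegment(0.0, step_time, initial_rate))
    if later_rate > 0:
        basal.append(InfusionSegment(step_time, space.horizon, later_rate))
    return Regimen(
        name=f"basal_{initial_rate:g}to{later_rate:g}_at{step_time:g}min",
        preop_events=space.loading_events,
        pca=PCAProgram(demand_dose=space.demand_dose, lockout=space.lockout, basal=tuple(basal)),
        demand_policy=DemandPolicy(mode="none"),
    )


@dataclass(frozen=True)
class CandidateResult:
    regimen: Regimen
    initial_rate: float
    step_time: float
    later_rate: float
    metrics: WindowMetrics
    scheduled_dose: float
    feasible: bool
    violation: float  # total minutes outside the window over the constraint interval


@dataclass(frozen=True)
class SearchResult:
    """Ranked candidates; ``selected`` is the winner (least total scheduled
    dose among feasible candidates, or the least-violating candidate if
    nothing is feasible — then ``feasible`` is False)."""

    candidates: tuple[CandidateResult, ...]
    selected: CandidateResult
    feasible: bool
    constraint_window: tuple[float, float]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rank": i + 1,
                    "regimen": c.regimen.name,
                    "initial_rate_ug_h": c.initial_rate,
                    "step_time_min": c.step_time,
                    "later_rate_ug_h": c.later_rate,
                    "feasible": c.feasible,
                    "violation_min": c.violation,
                    "scheduled_dose_ug": c.scheduled_dose,
                    "c_max_ng_ml": c.metrics.c_max,
                    "time_below_mec_min": c.metrics.time_below_mec,
                    "time_above_upper_min": c.metrics.time_above_upper,
                }
                for i, c in enumerate(self.candidates)
            ]
        )


#: durations shorter than this (min) count as numerically zero excursions
_VIOLATION_TOL = 1e-6


def search(
    space: SearchSpace,
    params: PKParameters | None = None,
    window: TherapeuticWindow | None = None,
    constraint_window: tuple[float, float] = (0.0, 60.0),
    t_start: float = -10.0,
    grid_step: float = 0.5,
) -> SearchResult:
    """Evaluate every candidate schedule and rank them.

    Feasibility means no excursion below the MEC and none above the upper
    bound within ``constraint_window`` under the no-demand scenario.  The
    result is deterministic and independent of enumeration order.
    """
    if params is None:
        params = PKParameters()
    if window is None:
        window = TherapeuticWindow()

    results: list[CandidateResult] = []
    for r1 in space.candidate_rates:
        for t_step in space.step_down_times:
            for r2 in space.candidate_rates:
                regimen = step_down_regimen(space, r1, t_step, r2)
                series = run(
                    regimen, params, t_start=t_start, t_end=space.horizon, grid_step=grid_step
                )
                m = window_metrics(series, window, *constraint_window)
                violation = m.time_below_mec + m.time_above_upper
                results.append(
                    CandidateResult(
                        regimen=regimen,
                        initial_rate=r1,
                        step_time=t_step,
                        later_rate=r2,
                        metrics=m,
                        scheduled_dose=series.expanded.scheduled_dose,
                        feasible=violation <= _VIOLATION_TOL,
                        violation=violation,
                    )
                )

    ranked = sorted(
        results,
        key=lambda c: (
            not c.feasible,
            c.scheduled_dose if c.feasible else c.violation,
            c.metrics.c_max,
            (c.initial_rate, c.step_time, c.later_rate),
        ),
    )
    return SearchResult(
        candidates=tuple(ranked),
        selected=ranked[0],
        feasible=ranked[0].feasible,
        constraint_window=tuple(constraint_window),
    )
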