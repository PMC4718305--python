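"""Dosing programs: boluses, infusion schedules, PCA demand/lockout logic.

A :class:`Regimen` bundles everything an infusion pump and clinician do:
scheduled boluses and zero-order infusion segments (e.g. a pre-emptive
loading dose before the end of surgery), the PCA program (demand bolus size,
lockout interval, basal infusion schedule), a demand-behaviour policy for
the simulated patient, and explicit rescue boluses.  ``expand_regimen``
flattens all of that into one time-ordered event list that the simulator
consumes.

The pump convention for the lockout is implemented: the lockout clock runs
from the last *granted* demand bolus, not from the last attempt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "BolusEvent",
    "InfusionSegment",
    "PCAProgram",
    "DemandPolicy",
    "Regimen",
    "Event",
    "ExpandedRegimen",
    "GrantResult",
    "grant_demands",
    "demand_attempts",
    "expand_regimen",
]


@dataclass(frozen=True)
class BolusEvent:
    """Instantaneous bolus of ``dose`` μg at time ``t`` (min)."""

    t: float
    dose: float

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError(f"bolus dose must be non-negative, got {self.dose}")


@dataclass(frozen=True)
class InfusionSegment:
    """Constant zero-order infusion at ``rate`` μg/h on [t_start, t_end) min."""

    t_start: float
    t_end: float
    rate: float

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError(f"require t_start < t_end, got [{self.t_start}, {self.t_end}]")
        if self.rate < 0:
            raise ValueError(f"infusion rate must be non-negative, got {self.rate}")

    @property
    def rate_per_min(self) -> float:
        return self.rate / 60.0

    @property
    def total_dose(self) -> float:
        """Drug delivered over the whole segment, μg."""
        return self.rate_per_min * (self.t_end - self.t_start)


@dataclass(frozen=True)
class PCAProgram:
    """Pump program: demand bolus size, lockout interval, basal schedule.

    ``basal`` segments must not overlap one another (a pump runs a single
    basal rate at a time).
    """

    demand_dose: float
    lockout: float
    basal: tuple[InfusionSegment, ...] = ()

    def __post_init__(self) -> None:
        if self.lockout <= 0:
            raise ValueError(f"lockout must be positive, got {self.lockout}")
        if self.demand_dose < 0:
            raise ValueError(f"demand_dose must be non-negative, got {self.demand_dose}")
        object.__setattr__(self, "basal", tuple(self.basal))
        segs = sorted(self.basal, key=lambda s: s.t_start)
        for a, b in zip(segs, segs[1:]):
            if b.t_start < a.t_end:
                raise ValueError(
                    f"overlapping basal segments: [{a.t_start}, {a.t_end}) and "
                    f"[{b.t_start}, {b.t_end})"
                )


@dataclass(frozen=True)
class DemandPolicy:
    """How the simulated patient presses the demand button.

    ``none`` — no demands (the deterministic base scenarios);
    ``worst_case`` — a press at PCA start and again the instant each lockout
    expires, the maximal-use envelope;
    ``poisson`` — presses as a homogeneous Poisson process with ``rate``
    attempts/h, reproducible for a fixed ``seed``.
    """

    mode: Literal["none", "worst_case", "poisson"] = "none"
    rate: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("none", "worst_case", "poisson"):
            raise ValueError(f"unknown demand policy mode {self.mode!r}")
        if self.mode == "poisson" and not (self.rate is not None and self.rate > 0):
            raise ValueError("poisson demand policy requires rate > 0 (attempts/h)")


@dataclass(frozen=True)
class Regimen:
    """A complete dosing program for one simulated patient.

    ``preop_events`` are scheduled boluses/infusions (typically before t=0,
    the end of surgery); ``rescue_events`` are explicit clinician boluses
    (pain itself is not modelled, so rescue times are user inputs).
    """

    name: str = "regimen"
    preop_events: tuple[BolusEvent | InfusionSegment, ...] = ()
    pca: PCAProgram | None = None
    demand_policy: DemandPolicy = field(default_factory=DemandPolicy)
    rescue_events: tuple[BolusEvent, ...] = ()
    pca_start: float = 0.0  # when the pump (demands + basal) becomes active

    def __post_init__(self) -> None:
        object.__setattr__(self, "preop_events", tuple(self.preop_events))
        object.__setattr__(self, "rescue_events", tuple(self.rescue_events))

    def scaled(self, factor: float) -> "Regimen":
        """All doses and rates multiplied by ``factor`` (linearity studies)."""
        if factor < 0:
            raise ValueError("scale factor must be non-negative")

        def _scale(ev):
            if isinstance(ev, BolusEvent):
                return replace(ev, dose=ev.dose * factor)
            return replace(ev, rate=ev.rate * factor)

        pca = self.pca
        if pca is not None:
            pca = PCAProgram(
                demand_dose=pca.demand_dose * factor,
                lockout=pca.lockout,
                basal=tuple(_scale(s) for s in pca.basal),
            )
        return replace(
            self,
            preop_events=tuple(_scale(e) for e in self.preop_events),
            pca=pca,
            rescue_events=tuple(_scale(e) for e in self.rescue_events),
        )


# ---------------------------------------------------------------------------
# demand / lockout logic


@dataclass(frozen=True)
class GrantResult:
    granted: tuple[BolusEvent, ...]
    rejected: tuple[tuple[float, str], ...]  # (attempt time, reason)


def grant_demands(pca: PCAProgram, attempts: Sequence[float]) -> GrantResult:
    """Apply the pump's lockout rule to a sorted sequence of attempt times.

    An attempt is granted iff no demand has been granted yet, or at least
    ``lockout`` minutes have elapsed since the last *granted* bolus.
    Rejected attempts are reported with the remaining lockout time.
    """
    attempts = list(attempts)
    if any(b < a for a, b in zip(attempts, attempts[1:])):
        raise ValueError("attempt times must be sorted ascending")
    granted: list[BolusEvent] = []
    rejected: list[tuple[float, str]] = []
    last_grant: float | None = None
    for t in attempts:
        if last_grant is None or t - last_grant >= pca.lockout:
            granted.append(BolusEvent(t=t, dose=pca.demand_dose))
            last_grant = t
        else:
            remaining = pca.lockout - (t - last_grant)
            rejected.append((t, f"lockout: {remaining:g} min remaining"))
    return GrantResult(granted=tuple(granted), rejected=tuple(rejected))


def demand_attempts(
    policy: DemandPolicy, pca: PCAProgram | None, t_start: float, horizon: float
) -> list[float]:
    """Generate demand-button press times on [t_start, horizon) per policy."""
    if policy.mode == "none" or pca is None or pca.demand_dose == 0:
        return []
    if policy.mode == "worst_case":
        n = max(0, math.floor((horizon - t_start) / pca.lockout) + 1)
        times = [t_start + k * pca.lockout for k in range(n)]
        return [t for t in times if t < horizon]
    # poisson
    rng = np.random.default_rng(policy.seed)
    rate_per_min = policy.rate / 60.0
    times: list[float] = []
    t = t_start
    while True:
        t += rng.exponential(1.0 / rate_per_min)
        if t >= horizon:
            break
        times.append(float(t))
    return times


# ---------------------------------------------------------------------------
# flattening


@dataclass(frozen=True)
class Event:
    """One entry of the flat event list.

    ``kind`` is ``"rate"`` (the total infusion rate changes to ``value``
    μg/min at ``t``) or ``"bolus"`` (``value`` μg added instantaneously).
    Simultaneous events are ordered rate-change first, then bolus, so a
    bolus at a rate breakpoint is carried by the new rate.
    """

    t: float
    kind: Literal["rate", "bolus"]
    value: float
    source: str = "scheduled"  # scheduled | demand | rescue


@dataclass(frozen=True)
class ExpandedRegimen:
    events: tuple[Event, ...]
    scheduled_dose: float  # μg delivered by non-demand events over the horizon
    attempts: tuple[float, ...] = ()
    rejected: tuple[tuple[float, str], ...] = ()


def _rate_breakpoints(segments: Sequence[InfusionSegment], horizon: float) -> list[Event]:
    """Total-rate step function of possibly several concurrent infusions."""
    deltas: dict[float, float] = {}
    for seg in segments:
        if seg.t_start >= horizon:
            continue
        deltas[seg.t_start] = deltas.get(seg.t_start, 0.0) + seg.rate_per_min
        end = min(seg.t_end, horizon)
        deltas[end] = deltas.get(end, 0.0) - seg.rate_per_min
    events = []
    level = 0.0
    for t in sorted(deltas):
        level += deltas[t]
        events.append(Event(t=t, kind="rate", value=max(level, 0.0)))
    return events


def expand_regimen(
    regimen: Regimen,
    horizon: float,
    policy_attempts: Sequence[float] | None = None,
) -> ExpandedRegimen:
    """Flatten a regimen into a sorted event list up to ``horizon`` minutes.

    ``policy_attempts`` overrides the demand policy with explicit attempt
    times; by default attempts are generated from ``regimen.demand_policy``
    starting at ``regimen.pca_start``.  The reported ``scheduled_dose``
    counts every non-demand μg delivered on [simulation start, horizon]:
    scheduled boluses, rescue boluses, and all infusion segments truncated
    at the horizon.
    """
    if horizon <= 0:
        raise ValueError(f"horizon must be positive, got {horizon}")

    segments = [e for e in regimen.preop_events if isinstance(e, InfusionSegment)]
    boluses = [(e, "scheduled") for e in regimen.preop_events if isinstance(e, BolusEvent)]
    boluses += [(e, "rescue") for e in regimen.rescue_events]

    if regimen.pca is not None:
        segments += [
            replace(s, t_start=max(s.t_start, regimen.pca_start))
            for s in regimen.pca.basal
            if s.t_end > regimen.pca_start
        ]

    if policy_attempts is None:
        attempts = demand_attempts(regimen.demand_policy, regimen.pca, regimen.pca_start, horizon)
    else:
        attempts = sorted(policy_attempts)
    rejected: tuple[tuple[float, str], ...] = ()
    if regimen.pca is not None and attempts:
        result = grant_demands(regimen.pca, attempts)
        boluses += [(e, "demand") for e in result.granted]
        rejected = result.rejected

    events = _rate_breakpoints(segments, horizon)
    events += [
        Event(t=e.t, kind="bolus", value=e.dose, source=src)
        for e, src in boluses
        if e.t <= horizon
    ]
    events.sort(key=lambda ev: (ev.t, 0 if ev.kind == "rate" else 1))

    scheduled = sum(e.dose for e, src in boluses if src != "demand" and e.t <= horizon)
    scheduled += sum(
        (min(s.t_end, horizon) - s.t_start) * s.rate_per_min
        for s in segments
        if s.t_start < horizon
    )
    return ExpandedRegimen(
        events=tuple(events),
        scheduled_dose=scheduled,
        attempts=tuple(attempts),
        rejected=rejected,
    )
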