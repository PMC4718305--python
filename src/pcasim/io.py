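"""JSON round-trip of regimens and PK parameters.

Regimen schema (all times in minutes, doses μg, rates μg/h)::

    {
      "name": "group_b",
      "events": [                       # scheduled (non-PCA) dosing
        {"type": "bolus", "t": -10, "dose": 50},
        {"type": "infusion", "t_start": -10, "t_end": 0, "rate": 300}
      ],
      "pca": {                          # optional
        "demand_dose": 10, "lockout": 15,
        "basal": [{"t_start": 0, "t_end": 60, "rate": 20}]
      },
      "demand_policy": {"mode": "none" | "worst_case" | "poisson",
                        "rate": 6, "seed": 1},
      "rescue": [{"t": 5, "dose": 25}]  # optional explicit rescue boluses
    }

``load_regimen(save_regimen(r)) == r`` for every valid regimen.  Schema
violations raise ``ValueError`` naming the offending field.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

from .events import BolusEvent, DemandPolicy, InfusionSegment, PCAProgram, Regimen
from .pk_core import PKParameters, TherapeuticWindow

__all__ = [
    "regimen_to_dict",
    "regimen_from_dict",
    "load_regimen",
    "save_regimen",
    "params_from_dict",
    "window_from_dict",
]


def _get(mapping: dict, key: str, context: str):
    try:
        return mapping[key]
    except KeyError:
        raise ValueError(f"regimen config: missing field {key!r} in {context}") from None


def _event_to_dict(ev: BolusEvent | InfusionSegment) -> dict:
    if isinstance(ev, BolusEvent):
        return {"type": "bolus", "t": ev.t, "dose": ev.dose}
    return {"type": "infusion", "t_start": ev.t_start, "t_end": ev.t_end, "rate": ev.rate}


def _event_from_dict(d: dict, context: str) -> BolusEvent | InfusionSegment:
    kind = _get(d, "type", context)
    if kind == "bolus":
        return BolusEvent(t=float(_get(d, "t", context)), dose=float(_get(d, "dose", context)))
    if kind == "infusion":
        return InfusionSegment(
            t_start=float(_get(d, "t_start", context)),
            t_end=float(_get(d, "t_end", context)),
            rate=float(_get(d, "rate", context)),
        )
    raise ValueError(f"regimen config: unknown event type {kind!r} in {context}")


def regimen_to_dict(regimen: Regimen) -> dict:
    d: dict = {
        "name": regimen.name,
        "events": [_event_to_dict(e) for e in regimen.preop_events],
    }
    if regimen.pca is not None:
        d["pca"] = {
            "demand_dose": regimen.pca.demand_dose,
            "lockout": regimen.pca.lockout,
            "basal": [
                {"t_start": s.t_start, "t_end": s.t_end, "rate": s.rate}
                for s in regimen.pca.basal
            ],
        }
    d["demand_policy"] = {
        k: v for k, v in asdict(regimen.demand_policy).items() if v is not None
    }
    if regimen.rescue_events:
        d["rescue"] = [{"t": e.t, "dose": e.dose} for e in regimen.rescue_events]
    return d


def regimen_from_dict(d: dict) -> Regimen:
    name = d.get("name", "regimen")
    events = tuple(
        _event_from_dict(e, f"events[{i}]") for i, e in enumerate(d.get("events", []))
    )
    pca = None
    if "pca" in d:
        p = d["pca"]
        pca = PCAProgram(
            demand_dose=float(_get(p, "demand_dose", "pca")),
            lockout=float(_get(p, "lockout", "pca")),
            basal=tuple(
                InfusionSegment(
                    t_start=float(_get(s, "t_start", f"pca.basal[{i}]")),
                    t_end=float(_get(s, "t_end", f"pca.basal[{i}]")),
                    rate=float(_get(s, "rate", f"pca.basal[{i}]")),
                )
                for i, s in enumerate(p.get("basal", []))
            ),
        )
    dp = d.get("demand_policy", {"mode": "none"})
    policy = DemandPolicy(
        mode=_get(dp, "mode", "demand_policy"),
        rate=float(dp["rate"]) if dp.get("rate") is not None else None,
        seed=int(dp["seed"]) if dp.get("seed") is not None else None,
    )
    rescue = tuple(
        BolusEvent(
            t=float(_get(e, "t", f"rescue[{i}]")), dose=float(_get(e, "dose", f"rescue[{i}]"))
        )
        for i, e in enumerate(d.get("rescue", []))
    )
    return Regimen(
        name=name, preop_events=events, pca=pca, demand_policy=policy, rescue_events=rescue
    )


def load_regimen(path: str | Path) -> Regimen:
    """Read a regimen from a JSON config file."""
    with open(path, encoding="utf-8") as fh:
        return regimen_from_dict(json.load(fh))


def save_regimen(regimen: Regimen, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(regimen_to_dict(regimen), fh, indent=2)
        fh.write("\n")


def params_from_dict(d: dict) -> PKParameters:
    """PK parameters from a JSON mapping; unknown keys are rejected."""
    allowed = {"v_central", "k10", "k12", "k13", "k21", "k31", "ke0"}
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"pk parameters: unknown field(s) {sorted(unknown)}")
    return PKParameters(**{k: float(v) for k, v in d.items()})


def window_from_dict(d: dict) -> TherapeuticWindow:
    allowed = {"mec", "upper", "reference"}
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"therapeutic window: unknown field(s) {sorted(unknown)}")
    return TherapeuticWindow(**d)
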