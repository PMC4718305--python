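"""Built-in study scenarios.

Two PCA programs for postoperative fentanyl analgesia after robot-assisted
laparoscopic prostatectomy, with the end of surgery at t = 0:

``group_a`` — conventional demand-only PCA: 50 μg IV bolus 10 min before
the end of surgery, then a 10 μg demand bolus with a 10-min lockout and no
basal infusion.

``group_b`` — model-based PCA: 50 μg loading delivered as a zero-order
infusion over the final 10 min of surgery (300 μg/h on [−10, 0]), then a
10 μg demand bolus with a 15-min lockout on top of a basal infusion of
20 μg/h for the first hour, stepped down to 10 μg/h thereafter.

Both default to no demand or rescue boluses, which is the deterministic
base case the published concentration curves describe.
"""

from __future__ import annotations

from .events import BolusEvent, DemandPolicy, InfusionSegment, PCAProgram, Regimen
from .pk_core import PKParameters, TherapeuticWindow

__all__ = ["group_a", "group_b", "get_scenario", "SCENARIOS", "DEFAULT_PARAMS", "DEFAULT_WINDOW"]

DEFAULT_PARAMS = PKParameters()
DEFAULT_WINDOW = TherapeuticWindow()

#: group B loading: 50 μg over the 10 min before the end of surgery
LOADING_INFUSION = InfusionSegment(t_start=-10.0, t_end=0.0, rate=300.0)


def group_a(horizon: float = 2880.0, demand_policy: DemandPolicy | None = None) -> Regimen:
    """Conventional demand-only PCA (50 μg preop bolus, 10 μg/10-min lockout)."""
    return Regimen(
        name="group_a",
        preop_events=(BolusEvent(t=-10.0, dose=50.0),),
        pca=PCAProgram(demand_dose=10.0, lockout=10.0, basal=()),
        demand_policy=demand_policy or DemandPolicy(mode="none"),
    )


def group_b(horizon: float = 2880.0, demand_policy: DemandPolicy | None = None) -> Regimen:
    """Model-based PCA (10-min loading infusion, 20→10 μg/h basal step-down)."""
    basal = [InfusionSegment(t_start=0.0, t_end=min(60.0, horizon), rate=20.0)]
    if horizon > 60.0:
        basal.append(InfusionSegment(t_start=60.0, t_end=horizon, rate=10.0))
    return Regimen(
        name="group_b",
        preop_events=(LOADING_INFUSION,),
        pca=PCAProgram(demand_dose=10.0, lockout=15.0, basal=tuple(basal)),
        demand_policy=demand_policy or DemandPolicy(mode="none"),
    )


SCENARIOS = {"group_a": group_a, "group_b": group_b}


def get_scenario(name: str, horizon: float = 2880.0, **kwargs) -> Regimen:
    """Look up a built-in scenario by name.

    Raises ``KeyError`` with the list of valid names for unknown scenarios.
    """
    try:
        builder = SCENARIOS[name]
    except KeyError:
        valid = ", ".join(sorted(SCENARIOS))
        raise KeyError(f"unknown scenario {name!r}; valid names: {valid}") from None
    return builder(horizon=horizon, **kwargs)
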