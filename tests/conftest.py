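"""Shared fixtures and the independent numerical oracle.

The oracle integrates the model's differential equations directly with an
adaptive Runge-Kutta method (scipy ``solve_ivp``), writing the right-hand
side by hand from the model definition — it shares no code with the
matrix-exponential engine it is used to check.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.integrate import solve_ivp

from pcasim import PKParameters

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def params() -> PKParameters:
    return PKParameters()


def ode_rhs(params: PKParameters):
    """Hand-written right-hand side of the three-compartment + effect-site ODEs."""
    p = params

    def rhs(t, x, rate):
        a1, a2, a3, ce = x
        return [
            rate - (p.k10 + p.k12 + p.k13) * a1 + p.k21 * a2 + p.k31 * a3,
            p.k12 * a1 - p.k21 * a2,
            p.k13 * a1 - p.k31 * a3,
            p.ke0 * (a1 / p.v_central - ce),
        ]

    return rhs


def ode_propagate(x0, params: PKParameters, rate: float, dt: float, dense: bool = False):
    """High-accuracy adaptive integration over one constant-rate segment."""
    if dt == 0:
        return np.asarray(x0, dtype=float)
    sol = solve_ivp(
        ode_rhs(params),
        (0.0, dt),
        x0,
        args=(rate,),
        method="DOP853",
        rtol=1e-11,
        atol=1e-13,
        dense_output=dense,
    )
    assert sol.success
    return sol if dense else sol.y[:, -1]


def ode_simulate_events(events, params: PKParameters, t_start: float, t_end: float, t_eval):
    """Oracle simulation of a flat event list; returns states at ``t_eval``.

    ``events`` are (t, kind, value) with kind "rate" (μg/min) or "bolus"
    (μg); rate changes apply before boluses at the same instant, as in the
    engine's documented tie-break.
    """
    events = sorted(events, key=lambda e: (e[0], 0 if e[1] == "rate" else 1))
    t_eval = np.asarray(t_eval, dtype=float)
    breaks = sorted({t_start, t_end, *[e[0] for e in events], *t_eval.tolist()})
    x = np.zeros(4)
    rate = 0.0
    out = {}
    for i, t in enumerate(breaks):
        if i > 0:
            x = ode_propagate(x, params, rate, t - breaks[i - 1])
        for et, kind, value in events:
            if et == t:
                if kind == "rate":
                    rate = value
                else:
                    x = x.copy()
                    x[0] += value
        out[t] = x.copy()
    return np.array([out[t] for t in t_eval])
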