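"""Linear three-compartment pharmacokinetic model with an effect site.

The drug amount moves between a central compartment (1) and two peripheral
compartments (2 = fast, 3 = slow) with first-order micro rate constants
``kij`` (from compartment *i* to *j*); elimination is first-order from the
central compartment (``k10``).  Plasma concentration is the central amount
divided by the central volume ``v_central``.  A hypothetical effect site
tracks plasma with first-order equilibration::

    dCe/dt = ke0 * (Cp - Ce)

The effect site carries a *concentration*, not an amount, so no effect-site
volume is needed and ``ke0`` appears exactly as written above.

Units: amounts in μg, volumes in L, times in minutes, rate constants in
1/min.  μg/L is numerically identical to ng/mL, so all concentrations are
reported as ng/mL without conversion.

Because the system is linear and dosing is piecewise constant (instantaneous
boluses plus zero-order infusion segments), propagation between dosing
events is *exact*: a matrix exponential of the augmented system, not a
fixed-step numerical integration.  This makes simulated curves independent
of the sampling grid and crossing times bit-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.linalg import expm

__all__ = [
    "PKParameters",
    "SystemState",
    "TherapeuticWindow",
    "build_rate_matrix",
    "propagate",
    "apply_bolus",
]

#: Fentanyl population parameters used throughout as defaults.
FENTANYL_DEFAULTS = dict(
    v_central=26.6,
    k10=0.0332,
    k12=0.172,
    k13=0.131,
    k21=0.1,
    k31=0.0177,
    ke0=0.147,
)


@dataclass(frozen=True)
class PKParameters:
    """Micro rate constants and central volume of the mammillary model.

    Defaults are the fentanyl adult population values used for the dosing
    design this package reproduces.

    Parameters
    ----------
    v_central : float
        Central (plasma) distribution volume, L.
    k10, k12, k13, k21, k31 : float
        First-order micro rate constants, 1/min.  ``kij`` moves drug from
        compartment *i* to compartment *j*; ``k10`` is elimination.
    ke0 : float
        Effect-site equilibration rate constant, 1/min.
    """

    v_central: float = FENTANYL_DEFAULTS["v_central"]
    k10: float = FENTANYL_DEFAULTS["k10"]
    k12: float = FENTANYL_DEFAULTS["k12"]
    k13: float = FENTANYL_DEFAULTS["k13"]
    k21: float = FENTANYL_DEFAULTS["k21"]
    k31: float = FENTANYL_DEFAULTS["k31"]
    ke0: float = FENTANYL_DEFAULTS["ke0"]

    def __post_init__(self) -> None:
        # v_central, k10 and ke0 must be strictly positive for the model to
        # make sense; intercompartmental constants may be zero, which
        # decouples the corresponding peripheral compartment.
        for name in ("v_central", "k10", "ke0"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise ValueError(f"PK parameter {name!r} must be strictly positive, got {value!r}")
        for name in ("k12", "k13", "k21", "k31"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value >= 0):
                raise ValueError(f"PK parameter {name!r} must be non-negative, got {value!r}")

    @property
    def clearance(self) -> float:
        """Elimination clearance ``k10 * v_central`` in L/min."""
        return self.k10 * self.v_central


@dataclass(frozen=True)
class SystemState:
    """Amounts in the three compartments plus effect-site concentration.

    ``t`` is minutes relative to the end of surgery (t = 0); ``a1``--``a3``
    are μg in the central, fast-peripheral and slow-peripheral compartments;
    ``ce`` is the effect-site concentration in ng/mL.
    """

    t: float = 0.0
    a1: float = 0.0
    a2: float = 0.0
    a3: float = 0.0
    ce: float = 0.0

    def plasma_concentration(self, params: PKParameters) -> float:
        """Plasma concentration a1 / v_central, ng/mL."""
        return self.a1 / params.v_central

    def as_vector(self) -> np.ndarray:
        """State vector (a1, a2, a3, ce) as a float array."""
        return np.array([self.a1, self.a2, self.a3, self.ce], dtype=float)

    @classmethod
    def from_vector(cls, t: float, x: np.ndarray) -> "SystemState":
        return cls(t=float(t), a1=float(x[0]), a2=float(x[1]), a3=float(x[2]), ce=float(x[3]))


@dataclass(frozen=True)
class TherapeuticWindow:
    """Concentration band the dosing design tries to stay inside.

    ``mec`` is the minimal effective (analgesic) concentration — the lower
    bound, 0.23 ng/mL for fentanyl here; ``upper`` the concentration above
    which side effects (respiratory depression) become a concern, default
    2.0 ng/mL.  ``reference`` selects which simulated concentration is
    compared against the bounds.
    """

    mec: float = 0.23
    upper: float = 2.0
    reference: str = "effect_site"  # or "plasma"

    def __post_init__(self) -> None:
        if not (0 < self.mec < self.upper):
            raise ValueError(f"require 0 < mec < upper, got mec={self.mec}, upper={self.upper}")
        if self.reference not in ("effect_site", "plasma"):
            raise ValueError(f"reference must be 'effect_site' or 'plasma', got {self.reference!r}")


def build_rate_matrix(params: PKParameters) -> np.ndarray:
    """Rate matrix A of the homogeneous system dx/dt = A x.

    State ordering is (a1, a2, a3, ce).  The 3×3 amount block conserves mass
    up to elimination: its column sums are (−k10, 0, 0).
    """
    p = params
    return np.array(
        [
            [-(p.k10 + p.k12 + p.k13), p.k21, p.k31, 0.0],
            [p.k12, -p.k21, 0.0, 0.0],
            [p.k13, 0.0, -p.k31, 0.0],
            [p.ke0 / p.v_central, 0.0, 0.0, -p.ke0],
        ]
    )


@lru_cache(maxsize=4096)
def _transition(params: PKParameters, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Exact transition for one piecewise-constant segment of length dt.

    Returns (Phi, psi) with x(t+dt) = Phi @ x(t) + rate * psi, where rate is
    the zero-order infusion rate into the central compartment (μg/min).
    Phi = e^{A dt}; psi = ∫₀^dt e^{A s} ds · e₁, both read off one matrix
    exponential of the 5×5 augmented system with unit forcing.
    """
    A = build_rate_matrix(params)
    M = np.zeros((5, 5))
    M[:4, :4] = A
    M[0, 4] = 1.0
    E = expm(M * dt)
    Phi = np.ascontiguousarray(E[:4, :4])
    psi = np.ascontiguousarray(E[:4, 4])
    Phi.setflags(write=False)
    psi.setflags(write=False)
    return Phi, psi


def propagate_vector(
    x: np.ndarray, params: PKParameters, infusion_rate: float, dt: float
) -> np.ndarray:
    """Exact propagation of a raw state vector over dt minutes.

    ``infusion_rate`` is μg/min, constant over the step.  The hot path of
    the event-driven simulator; transitions are cached per (params, dt).
    """
    if dt < 0:
        raise ValueError(f"dt must be non-negative, got {dt}")
    if infusion_rate < 0:
        raise ValueError(f"infusion_rate must be non-negative, got {infusion_rate}")
    if dt == 0:
        return np.asarray(x, dtype=float).copy()
    Phi, psi = _transition(params, float(dt))
    return Phi @ x + infusion_rate * psi


def propagate(
    state: SystemState, params: PKParameters, infusion_rate: float = 0.0, dt: float = 0.0
) -> SystemState:
    """Advance the system dt minutes under a constant infusion rate (μg/min).

    The solution is exact (matrix exponential with constant forcing into the
    central compartment); ``dt=0`` returns the input state unchanged.
    """
    if dt == 0:
        return state
    x = propagate_vector(state.as_vector(), params, infusion_rate, dt)
    return SystemState.from_vector(state.t + dt, x)


def apply_bolus(state: SystemState, dose: float) -> SystemState:
    """Instantaneous intravenous bolus: add ``dose`` μg to the central amount.

    Peripheral amounts, effect-site concentration and time are unchanged.
    """
    if dose < 0:
        raise ValueError(f"bolus dose must be non-negative, got {dose}")
    return replace(state, a1=state.a1 + dose)
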