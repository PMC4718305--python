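"""Core propagator: structure, closed forms, exactness, conservation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pcasim import PKParameters, SystemState, TherapeuticWindow, apply_bolus, build_rate_matrix, propagate
from pcasim.pk_core import propagate_vector

from conftest import ode_propagate


class TestRateMatrix:
    def test_default_structure(self, params):
        A = build_rate_matrix(params)
        assert A.shape == (4, 4)
        assert A[0, 0] == pytest.approx(-0.3362)  # -(k10 + k12 + k13)
        assert A[1, 0] == params.k12 and A[0, 1] == params.k21
        assert A[2, 0] == params.k13 and A[0, 2] == params.k31
        assert A[3, 0] == pytest.approx(params.ke0 / params.v_central)
        assert A[3, 3] == -params.ke0

    @given(
        st.floats(0.01, 1.0), st.floats(0.0, 1.0), st.floats(0.0, 1.0),
        st.floats(0.0, 1.0), st.floats(0.0, 1.0),
    )
    def test_amount_block_mass_balance(self, k10, k12, k13, k21, k31):
        """Column sums of the 3x3 amount block are (-k10, 0, 0): transfers
        conserve drug, only elimination removes it."""
        p = PKParameters(v_central=20.0, k10=k10, k12=k12, k13=k13, k21=k21, k31=k31, ke0=0.1)
        A = build_rate_matrix(p)[:3, :3]
        np.testing.assert_allclose(A.sum(axis=0), [-k10, 0.0, 0.0], atol=1e-15)

    def test_zero_transfer_decouples_periphery(self):
        p = PKParameters(k12=0.0, k13=0.0)
        A = build_rate_matrix(p)
        assert A[0, 0] == -p.k10
        assert A[1, 0] == A[2, 0] == 0.0

    @pytest.mark.parametrize("field", ["v_central", "k10", "ke0"])
    def test_nonpositive_core_parameter_rejected(self, field):
        with pytest.raises(ValueError, match=field):
            PKParameters(**{field: 0.0})

    def test_negative_transfer_rejected(self):
        with pytest.raises(ValueError, match="k21"):
            PKParameters(k21=-0.1)


class TestPropagate:
    def test_dt_zero_is_identity(self, params):
        s = SystemState(t=5.0, a1=10.0, a2=3.0, a3=1.0, ce=0.2)
        assert propagate(s, params, infusion_rate=1.0, dt=0.0) is s

    def test_mono_exponential_closed_form(self):
        """With both transfer constants zero the central compartment decays
        mono-exponentially: after one time constant a1 = a1(0)/e."""
        p = PKParameters(k12=0.0, k13=0.0)
        s = propagate(SystemState(a1=50.0), p, infusion_rate=0.0, dt=1.0 / p.k10)
        assert s.a1 == pytest.approx(50.0 / np.e, rel=1e-12)
        assert s.a2 == 0.0 and s.a3 == 0.0

    def test_constant_infusion_steady_state(self, params):
        """Long constant-rate infusion approaches cp = rate / clearance."""
        rate = 20.0 / 60.0  # 20 ug/h in ug/min
        s = propagate(SystemState(), params, infusion_rate=rate, dt=50_000.0)
        assert s.plasma_concentration(params) == pytest.approx(rate / params.clearance, rel=1e-6)
        assert s.plasma_concentration(params) == pytest.approx(0.3775, abs=1e-4)

    def test_validation(self, params):
        s = SystemState(a1=1.0)
        with pytest.raises(ValueError):
            propagate(s, params, infusion_rate=-1.0, dt=1.0)
        with pytest.raises(ValueError):
            propagate(s, params, infusion_rate=0.0, dt=-1.0)

    @given(
        st.lists(st.floats(0.0, 100.0), min_size=4, max_size=4),
        st.lists(st.floats(0.0, 100.0), min_size=4, max_size=4),
        st.floats(0.0, 5.0),
        st.floats(0.01, 120.0),
    )
    def test_linearity_and_superposition(self, xs, ys, rate, dt):
        """Affine structure of the exact step: the response to a summed state
        equals the sum of responses, and the forcing enters additively."""
        p = PKParameters()
        x, y = np.array(xs), np.array(ys)
        both = propagate_vector(x + y, p, 0.0, dt)
        np.testing.assert_allclose(
            both, propagate_vector(x, p, 0.0, dt) + propagate_vector(y, p, 0.0, dt),
            rtol=1e-9, atol=1e-9,
        )
        forced = propagate_vector(x, p, rate, dt)
        np.testing.assert_allclose(
            forced,
            propagate_vector(x, p, 0.0, dt) + propagate_vector(np.zeros(4), p, rate, dt),
            rtol=1e-9, atol=1e-9,
        )

    @given(
        st.lists(st.floats(0.0, 100.0), min_size=4, max_size=4),
        st.floats(0.0, 5.0),
        st.floats(0.0, 200.0),
    )
    def test_non_negativity(self, xs, rate, dt):
        out = propagate_vector(np.array(xs), PKParameters(), rate, dt)
        assert (out >= -1e-12).all()

    def test_matches_ode_oracle_single_segment(self, params):
        x0 = np.array([30.0, 5.0, 2.0, 0.4])
        got = propagate_vector(x0, params, 0.5, 37.3)
        want = ode_propagate(x0, params, 0.5, 37.3)
        np.testing.assert_allclose(got, want, rtol=1e-8)


class TestBolus:
    def test_jump_equals_dose_over_volume(self, params):
        s = apply_bolus(SystemState(), 50.0)
        assert s.plasma_concentration(params) == pytest.approx(50.0 / 26.6)
        assert s.plasma_concentration(params) == pytest.approx(1.8797, abs=5e-5)
        assert (s.a2, s.a3, s.ce, s.t) == (0.0, 0.0, 0.0, 0.0)

    def test_zero_dose_identity_and_superposition(self):
        s = SystemState(a1=7.0, a2=1.0, ce=0.1)
        assert apply_bolus(s, 0.0) == s
        twice = apply_bolus(apply_bolus(s, 12.5), 12.5)
        assert twice == apply_bolus(s, 25.0)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            apply_bolus(SystemState(), -1.0)


class TestEffectSite:
    def test_lag_after_bolus(self, params):
        """Effect-site concentration peaks later and lower than plasma."""
        s = apply_bolus(SystemState(), 50.0)
        ts = np.arange(0.0, 30.0, 0.05)
        x = s.as_vector()
        cps, ces = [], []
        for _ in ts:
            cps.append(x[0] / params.v_central)
            ces.append(x[3])
            x = propagate_vector(x, params, 0.0, 0.05)
        t_cp, t_ce = ts[np.argmax(cps)], ts[np.argmax(ces)]
        assert t_ce > t_cp
        assert max(ces) < max(cps)

    def test_equilibrates_at_steady_state(self, params):
        s = propagate(SystemState(), params, infusion_rate=0.5, dt=100_000.0)
        assert s.ce == pytest.approx(s.plasma_concentration(params), rel=1e-6)


class TestMassBalance:
    def test_dose_accounted_over_48h(self, params):
        """Administered drug equals what remains in the compartments plus
        what elimination removed (k10 * integral of a1), to 0.1%."""
        dt = 0.05
        ts = np.arange(0.0, 2880.0 + dt, dt)
        rate = 20.0 / 60.0
        x = np.array([50.0, 0.0, 0.0, 0.0])  # bolus at t=0, then constant infusion
        a1 = np.empty(len(ts))
        for i in range(len(ts)):
            a1[i] = x[0]
            if i < len(ts) - 1:
                x = propagate_vector(x, params, rate, dt)
        administered = 50.0 + rate * ts[-1]
        eliminated = params.k10 * np.trapezoid(a1, ts)
        remaining = x[0] + x[1] + x[2]
        assert administered == pytest.approx(eliminated + remaining, rel=1e-3)


def test_therapeutic_window_validation():
    with pytest.raises(ValueError):
        TherapeuticWindow(mec=2.0, upper=1.0)
    with pytest.raises(ValueError):
        TherapeuticWindow(reference="urine")
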