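"""Unit and property tests of the compartmental delay model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad, solve_ivp

from losartan_pkpd.model import (DoseRegimen, IntegrityError,
                                 InvalidParameterError, PKParameters,
                                 dose_mg_to_nmol, model_rhs, pyloric_rate,
                                 simulate)


def make_params(**kw):
    base = dict(a=4.5, b=3.95, k_a=4.3, k_m=1.056, T=0.745, CL_p=30.5,
                CL_m=17.5, Q=112.6, Vp1=53.2, Vp2=112.7, Vm=58.4)
    base.update(kw)
    return PKParameters(**base)


class TestPyloricRate:
    def test_period_matches_motor_complex_range(self):
        # 2*pi/b at b = 3.95 rad/h lies inside the 85-115 min cycle range
        period_min = 2 * math.pi / 3.95 * 60
        assert 85 < period_min < 115

    def test_valve_closed_at_sine_minimum(self):
        b = 3.95
        t_closed = (3 * math.pi / 2) / b  # sin(b t) = -1
        assert pyloric_rate(t_closed, a=5.0, b=b) == pytest.approx(0.0, abs=1e-12)

    def test_time_average_is_half_amplitude(self):
        a, b = 4.5, 3.95
        period = 2 * math.pi / b
        mean, _ = quad(lambda t: pyloric_rate(t, a, b), 0, period)
        assert mean / period == pytest.approx(a / 2, rel=1e-9)

    @pytest.mark.parametrize("a,b", [(0, 1), (-1, 1), (1, 0), (1, -2)])
    def test_invalid_parameters_rejected(self, a, b):
        with pytest.raises(InvalidParameterError):
            pyloric_rate(1.0, a, b)

    @given(t=st.floats(0, 1000), a=st.floats(0.01, 50), b=st.floats(0.01, 50))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_rate_bounded_and_periodic(self, t, a, b):
        r = pyloric_rate(t, a, b)
        assert 0.0 <= r <= a
        period = 2 * math.pi / b
        assert pyloric_rate(t + period, a, b) == pytest.approx(r, rel=1e-6, abs=1e-9)


class TestModelRhs:
    def test_empty_system_is_at_equilibrium(self):
        d = model_rhs(1.3, np.zeros(7), 0.0, make_params())
        assert np.all(d == 0)

    def test_zero_conversion_leaves_only_metabolite_elimination(self):
        p = make_params(k_m=0.0)
        state = np.array([10.0, 5.0, 7.0, 3.0, 11.0, 0.0, 0.0])
        d = model_rhs(0.7, state, 123.0, p)  # delayed A_c irrelevant at k_m=0
        assert d[4] == pytest.approx(-(p.CL_m / p.Vm) * state[4], rel=1e-12)

    def test_closed_system_conserves_mass_in_the_derivative(self):
        # CL_p = CL_m = 0 and T = 0 (delayed A_c = current A_c): amounts sum to 0 rate
        p = make_params(CL_p=0.0, CL_m=0.0, T=0.0)
        rng = np.random.default_rng(0)
        for _ in range(5):
            state = rng.uniform(0, 100, size=7)
            d = model_rhs(rng.uniform(0, 24), state, state[2], p)
            assert d[:5].sum() == pytest.approx(0.0, abs=1e-10 * state[:5].sum())


class TestSimulate:
    def test_zero_dose_gives_zero_concentrations(self):
        reg = DoseRegimen(events=((0.0, 0.0),))
        res = simulate(make_params(), reg, n_out=101)
        assert np.all(res.Cp == 0) and np.all(res.Cm == 0)

    def test_metabolite_zero_during_transit_delay(self, wt_sim, wt_params):
        mask = wt_sim.t <= wt_params.T
        assert np.all(wt_sim.Cm[mask] == 0)
        assert wt_sim.Cm[-1] > 0

    def test_dose_linearity_pointwise(self, wt_params):
        r1 = simulate(wt_params, DoseRegimen.single_oral(50.0), n_out=241)
        r2 = simulate(wt_params, DoseRegimen.single_oral(100.0), n_out=241)
        scale = np.max(r1.Cp)
        assert np.allclose(r2.Cp, 2 * r1.Cp, atol=2e-6 * scale)
        assert np.allclose(r2.Cm, 2 * r1.Cm, atol=2e-6 * scale)
        assert r2.auc_p == pytest.approx(2 * r1.auc_p, rel=1e-6)
        assert r2.auc_m == pytest.approx(2 * r1.auc_m, rel=1e-6)

    def test_mass_conserved_without_clearance_or_delay(self):
        p = make_params(CL_p=0.0, CL_m=0.0, T=0.0)
        reg = DoseRegimen.single_oral(50.0)
        res = simulate(p, reg, n_out=241)
        total = res.states[:, :5].sum(axis=1)
        assert np.allclose(total, reg.total_amount, rtol=1e-6)

    def test_delay_bookkeeping_mass_in_transit(self):
        # with zero clearance and T > 0, the missing mass at time t is
        # exactly the conversion flux integrated over the last T hours
        p = make_params(CL_p=0.0, CL_m=0.0, T=0.5)
        reg = DoseRegimen.single_oral(50.0)
        res = simulate(p, reg, n_out=2401)
        A_c = res.state("A_c")
        cum = np.concatenate(([0.0], np.cumsum(np.diff(res.t) * (A_c[1:] + A_c[:-1]) / 2)))
        in_transit = p.k_m * (cum - np.interp(res.t - p.T, res.t, cum, left=0.0))
        total = res.states[:, :5].sum(axis=1)
        assert np.allclose(total + in_transit, reg.total_amount,
                           rtol=2e-3)

    def test_bateman_closed_form_in_degenerate_limit(self):
        # Q = 0, T = 0, dose into the intestine: parent follows the
        # one-compartment oral-absorption (Bateman) solution with
        # elimination rate k_m + CL_p/Vp1
        D = dose_mg_to_nmol(50.0)
        p = make_params(Q=0.0, T=0.0, k_a=2.0, k_m=0.5, CL_p=10.0, Vp1=20.0)
        reg = DoseRegimen(events=((0.0, D),), into="intestine")
        res = simulate(p, reg, t_end=24.0, n_out=481)
        ke = p.k_m + p.CL_p / p.Vp1
        exact = (D * p.k_a / (p.Vp1 * (ke - p.k_a))) * (np.exp(-p.k_a * res.t)
                                                        - np.exp(-ke * res.t))
        err = np.abs(res.Cp - exact)
        big = exact > 1e-3 * exact.max()
        assert np.max(err[big] / exact[big]) < 1e-6

    def test_zero_delay_matches_plain_ode_oracle(self):
        p = make_params(T=0.0)
        reg = DoseRegimen.single_oral(50.0)
        res = simulate(p, reg, n_out=241)

        def rhs(t, y):
            return model_rhs(t, y, y[2], p)

        y0 = np.zeros(7)
        y0[0] = reg.total_amount
        sol = solve_ivp(rhs, (0, 24), y0, method="LSODA", rtol=1e-10, atol=1e-12,
                        t_eval=res.t)
        Cp_ref = sol.y[2] / p.Vp1
        Cm_ref = sol.y[4] / p.Vm
        assert np.max(np.abs(res.Cp - Cp_ref)) < 1e-6 * Cp_ref.max()
        assert np.max(np.abs(res.Cm - Cm_ref)) < 1e-6 * Cm_ref.max()

    def test_metabolite_exposure_monotone_in_conversion_rate(self):
        reg = DoseRegimen.single_oral(50.0)
        aucs = [simulate(make_params(k_m=km), reg, n_out=97).auc_m
                for km in (0.0, 0.5, 1.0, 1.5, 2.0)]
        assert aucs[0] == 0.0
        assert all(x2 >= x1 for x1, x2 in zip(aucs, aucs[1:]))

    def test_input_validation(self):
        p = make_params()
        with pytest.raises(InvalidParameterError):
            simulate(p, DoseRegimen.single_oral(50.0, time_h=5.0), t_end=4.0)
        with pytest.raises(InvalidParameterError):
            simulate(p, DoseRegimen.single_oral(50.0), n_out=1)
        with pytest.raises(InvalidParameterError):
            PKParameters(a=-1, b=3.95, k_a=1, k_m=1, T=0, CL_p=1, CL_m=1,
                         Q=1, Vp1=1, Vp2=1, Vm=1)
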