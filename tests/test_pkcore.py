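import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polybtdm import (
    DosingRegimen,
    InfusionEvent,
    PKParameters,
    auc_numeric,
    auc_ss_daily,
    concentration,
    disposition_constants,
    traditional_regimen,
)
from polybtdm.pkcore import InvalidIntervalError, InvalidParameterError

from conftest import ode_concentration

positive = st.floats(min_value=0.05, max_value=50.0, allow_nan=False)


class TestDispositionConstants:
    def test_one_compartment_limit(self):
        # Q = 0 decouples the peripheral compartment: single exponential
        # with rate CL/V1, beta branch collapses to zero.
        dc = disposition_constants(PKParameters(cl=2.0, v1=10.0, q=0.0, v2=1.0))
        assert dc.alpha == pytest.approx(0.2, rel=1e-12)
        assert dc.beta == pytest.approx(0.0, abs=1e-15)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(cl=positive, v1=positive, q=positive, v2=positive)
    def test_product_and_sum_identities(self, cl, v1, q, v2):
        p = PKParameters(cl, v1, q, v2)
        dc = disposition_constants(p)
        assert dc.alpha >= dc.beta > 0
        assert dc.alpha * dc.beta == pytest.approx(cl * q / (v1 * v2), rel=1e-10)
        assert dc.alpha + dc.beta == pytest.approx(cl / v1 + q / v1 + q / v2, rel=1e-12)

    def test_eigenvalue_oracle(self, params):
        # Exponents must equal (minus) the eigenvalues of the 2x2
        # compartmental rate matrix, computed independently.
        k10, k12, k21 = (
            params.cl / params.v1,
            params.q / params.v1,
            params.q / params.v2,
        )
        A = np.array([[-(k10 + k12), k21], [k12, -k21]])
        eig = np.sort(-np.linalg.eigvals(A))
        dc = disposition_constants(params)
        assert dc.beta == pytest.approx(eig[0], rel=1e-12)
        assert dc.alpha == pytest.approx(eig[1], rel=1e-12)

    def test_invalid_parameters_raise(self):
        with pytest.raises(InvalidParameterError):
            PKParameters(cl=-1.0, v1=10.0, q=1.0, v2=10.0)
        with pytest.raises(InvalidParameterError):
            PKParameters(cl=1.0, v1=0.0, q=1.0, v2=10.0)


class TestConcentration:
    def test_zero_before_first_dose(self, params, regimen_70kg):
        assert concentration(params, regimen_70kg, 0.0) == 0.0

    def test_matches_ode_oracle(self, params, regimen_70kg):
        rng = np.random.default_rng(42)
        times = np.sort(rng.uniform(0.1, 48.0, size=50))
        closed = concentration(params, regimen_70kg, times)
        numeric = ode_concentration(params, regimen_70kg, times)
        assert np.allclose(closed, numeric, rtol=1e-6)

    def test_matches_ode_oracle_near_degenerate(self):
        # alpha ~ beta when k12 -> 0 and k10 = k21: exercises the
        # critically damped limiting form.
        p = PKParameters(cl=2.0, v1=10.0, q=1e-7, v2=5e-7)
        reg = DosingRegimen((InfusionEvent(0.0, 2.0, 100.0),))
        times = np.array([0.5, 1.0, 2.0, 3.0, 6.0, 12.0])
        closed = concentration(p, reg, times)
        # one-compartment analytic reference (peripheral negligible)
        k = 0.2
        rate = 50.0
        ref = np.where(
            times <= 2.0,
            rate / (k * 10.0) * (1 - np.exp(-k * times)),
            rate / (k * 10.0) * (1 - np.exp(-k * 2.0)) * np.exp(-k * (times - 2.0)),
        )
        assert np.allclose(closed, ref, rtol=1e-4)

    def test_linearity_in_dose(self, params, regimen_70kg):
        t = np.linspace(0.5, 40, 17)
        c1 = concentration(params, regimen_70kg, t)
        c2 = concentration(params, regimen_70kg.scaled(2.0), t)
        assert np.allclose(c2, 2.0 * c1, rtol=1e-12)

    def test_superposition_over_events(self, params):
        e1 = InfusionEvent(0.0, 2.0, 175.0)
        e2 = InfusionEvent(12.0, 1.0, 105.0)
        t = np.linspace(0.0, 30.0, 40)
        both = concentration(params, DosingRegimen((e1, e2)), t)
        split = concentration(params, DosingRegimen((e1,)), t) + concentration(
            params, DosingRegimen((e2,)), t
        )
        assert np.allclose(both, split, rtol=1e-12)

    def test_continuity_at_infusion_end(self, params, single_infusion):
        eps = 1e-7
        left = concentration(params, single_infusion, 2.0 - eps)
        right = concentration(params, single_infusion, 2.0 + eps)
        assert right == pytest.approx(left, rel=1e-5)

    def test_trough_excludes_dose_starting_now(self, params):
        # a sample at exactly a dose's start time sees nothing of it
        reg_with = traditional_regimen(70.0)
        reg_without = DosingRegimen(
            tuple(e for e in reg_with.events if e.start < 24.0)
        )
        assert concentration(params, reg_with, 24.0) == pytest.approx(
            concentration(params, reg_without, 24.0), rel=1e-14
        )


class TestAUC:
    def test_steady_state_equals_dose_over_cl(self, params):
        # >= 10 days of q12h dosing, then one full dosing day
        reg = traditional_regimen(70.0, n_doses=30)
        daily_dose = 2 * 105.0
        auc = auc_numeric(params, reg, 288.0, 312.0)
        assert auc == pytest.approx(daily_dose / params.cl, rel=1e-3)

    def test_empty_regimen_zero(self, params):
        assert auc_numeric(params, DosingRegimen(()), 0.0, 24.0) == 0.0

    def test_against_dense_trapezoid(self, params, regimen_70kg):
        t = np.arange(0.0, 24.0 + 1e-9, 1.0 / 60.0)  # 1-minute grid
        c = concentration(params, regimen_70kg, t)
        trapz = np.trapezoid(c, t)
        assert auc_numeric(params, regimen_70kg, 0.0, 24.0) == pytest.approx(
            trapz, rel=5e-3
        )

    def test_invalid_interval_raises(self, params, regimen_70kg):
        with pytest.raises(InvalidIntervalError):
            auc_numeric(params, regimen_70kg, 24.0, 12.0)

    def test_auc_ss_daily_identities(self):
        assert auc_ss_daily(0.437, 75 * 0.437) == pytest.approx(75.0, rel=1e-12)
        assert auc_ss_daily(0.0276, 2.0) == pytest.approx(72.46, abs=0.005)
        assert auc_ss_daily(1.5, 0.0) == 0.0
        with pytest.raises(InvalidParameterError):
            auc_ss_daily(0.0, 100.0)
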