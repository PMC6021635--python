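import numpy as np
import pytest

from polybtdm import (
    DEFAULT_MODEL,
    DosingRegimen,
    InfusionEvent,
    PKParameters,
    traditional_regimen,
)


@pytest.fixture
def params():
    """A plausible adult absolute parameter set (70-kg subject scale)."""
    return PKParameters(cl=1.93, v1=17.5, q=4.2, v2=17.5)


@pytest.fixture
def model():
    return DEFAULT_MODEL


@pytest.fixture
def regimen_70kg():
    """Traditional regimen for a 70-kg adult: 175 mg load / 2 h, 105 mg q12h / 1 h."""
    return traditional_regimen(70.0)


@pytest.fixture
def regimen_1kg():
    return traditional_regimen(1.0)


@pytest.fixture
def single_infusion():
    return DosingRegimen((InfusionEvent(start=0.0, duration=2.0, amount=175.0),))


def ode_concentration(params, regimen, times):
    """Numeric oracle: integrate the two-compartment ODE system.

    dA1/dt = R(t) - (k10+k12) A1 + k21 A2 ; dA2/dt = k12 A1 - k21 A2,
    C = A1/V1.  Independent of the closed-form path under test.
    """
    from scipy.integrate import solve_ivp

    k10 = params.cl / params.v1
    k12 = params.q / params.v1
    k21 = params.q / params.v2

    def rate_in(t):
        return sum(
            e.rate for e in regimen.events if e.start <= t < e.start + e.duration
        )

    def rhs(t, a):
        return [
            rate_in(t) - (k10 + k12) * a[0] + k21 * a[1],
            k12 * a[0] - k21 * a[1],
        ]

    t_end = float(max(times)) if len(times) else 0.0
    breaks = sorted(
        {b for e in regimen.events for b in (e.start, e.start + e.duration) if b < t_end}
    )
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        [0.0, 0.0],
        method="LSODA",
        t_eval=np.asarray(times, dtype=float),
        rtol=1e-10,
        atol=1e-12,
        max_step=0.5,
    )
    return sol.y[0] / params.v1
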