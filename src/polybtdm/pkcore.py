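"""Closed-form linear two-compartment infusion kinetics.

Plasma concentration for a drug following linear two-compartment
disposition (central volume ``V1``, peripheral volume ``V2``, clearance
``CL``, intercompartmental clearance ``Q``) under any sequence of
zero-order infusions, evaluated analytically by superposition of the
biexponential unit response.  Time is in hours, amounts in mg, volumes
in litres and concentrations in mg/L throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import integrate

__all__ = [
    "PKParameters",
    "InfusionEvent",
    "DosingRegimen",
    "SamplingSchedule",
    "DispositionConstants",
    "disposition_constants",
    "concentration",
    "auc_numeric",
    "auc_ss_daily",
]

# Relative closeness of the two macro rate constants below which the
# repeated-eigenvalue (critically damped) limiting form is used.
_EIGEN_DEGENERACY_RTOL = 1e-10


class InvalidParameterError(ValueError):
    """A PK parameter or input violates its positivity/ordering constraint."""


@dataclass(frozen=True)
class PKParameters:
    """Two-compartment disposition parameters of one subject.

    Attributes
    ----------
    cl : float
        Clearance from the central compartment, L/h.
    v1 : float
        Central (plasma) volume of distribution, L.
    q : float
        Intercompartmental clearance, L/h.  ``q = 0`` collapses the
        model to one compartment.
    v2 : float
        Peripheral volume of distribution, L.
    """

    cl: float
    v1: float
    q: float
    v2: float

    def __post_init__(self) -> None:
        if not (self.cl > 0 and self.v1 > 0 and self.v2 > 0):
            raise InvalidParameterError(
                f"cl, v1, v2 must be strictly positive, got "
                f"cl={self.cl}, v1={self.v1}, v2={self.v2}"
            )
        if self.q < 0:
            raise InvalidParameterError(f"q must be non-negative, got q={self.q}")

    def as_array(self) -> np.ndarray:
        return np.array([self.cl, self.v1, self.q, self.v2], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "PKParameters":
        cl, v1, q, v2 = (float(x) for x in arr)
        return cls(cl=cl, v1=v1, q=q, v2=v2)

    def scaled(self, factor: float) -> "PKParameters":
        """Scale all four parameters by ``factor`` (linear weight scaling)."""
        return PKParameters(
            cl=self.cl * factor, v1=self.v1 * factor, q=self.q * factor, v2=self.v2 * factor
        )


@dataclass(frozen=True)
class InfusionEvent:
    """A single zero-order intravenous infusion.

    ``start`` is hours since the first dose, ``duration`` the infusion
    length in hours and ``amount`` the dose in mg.
    """

    start: float
    duration: float
    amount: float

    def __post_init__(self) -> None:
        if self.start < 0:
            raise InvalidParameterError(f"infusion start must be >= 0, got {self.start}")
        if self.duration <= 0:
            raise InvalidParameterError(f"infusion duration must be > 0, got {self.duration}")
        if self.amount < 0:
            raise InvalidParameterError(f"infusion amount must be >= 0, got {self.amount}")

    @property
    def rate(self) -> float:
        """Infusion rate in mg/h."""
        return self.amount / self.duration


@dataclass(frozen=True)
class DosingRegimen:
    """An ordered sequence of infusion events."""

    events: tuple[InfusionEvent, ...]

    def __post_init__(self) -> None:
        ev = tuple(self.events)
        if any(b.start < a.start for a, b in zip(ev, ev[1:])):
            ev = tuple(sorted(ev, key=lambda e: e.start))
        object.__setattr__(self, "events", ev)

    def __len__(self) -> int:
        return len(self.events)

    def scaled(self, factor: float) -> "DosingRegimen":
        """Multiply every infusion amount by ``factor`` (dose linearity)."""
        return DosingRegimen(
            tuple(
                InfusionEvent(e.start, e.duration, e.amount * factor) for e in self.events
            )
        )

    def total_amount(self, t0: float = 0.0, t1: float = np.inf) -> float:
        """Summed dose of events starting in ``[t0, t1)``, mg."""
        return sum(e.amount for e in self.events if t0 <= e.start < t1)

    def event_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(starts, durations, rates) as float arrays — fast-path layout."""
        if not self.events:
            z = np.empty(0)
            return z, z.copy(), z.copy()
        starts = np.array([e.start for e in self.events])
        durs = np.array([e.duration for e in self.events])
        rates = np.array([e.rate for e in self.events])
        return starts, durs, rates


@dataclass(frozen=True)
class SamplingSchedule:
    """Strictly increasing blood-sampling times, hours since first dose."""

    times: tuple[float, ...]

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.times)
        if any(x < 0 for x in t):
            raise InvalidParameterError(f"sampling times must be >= 0, got {t}")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise InvalidParameterError(f"sampling times must be strictly increasing, got {t}")
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return len(self.times)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)


class DispositionConstants(NamedTuple):
    """Macro constants of the biexponential disposition.

    ``alpha >= beta > 0`` are the exponents (1/h) and ``coef_alpha``,
    ``coef_beta`` the unit-bolus concentration coefficients (1/L), so the
    unit impulse response is ``coef_alpha*exp(-alpha*t) + coef_beta*exp(-beta*t)``.
    ``k21 = Q/V2`` is carried for the degenerate-eigenvalue limit form.
    """

    alpha: float
    beta: float
    coef_alpha: float
    coef_beta: float
    k21: float
    degenerate: bool


def disposition_constants(params: PKParameters) -> DispositionConstants:
    """Macro rate constants and bolus coefficients from micro parameters.

    The exponents are the eigenvalues of the compartmental rate matrix:
    ``alpha + beta = k10 + k12 + k21`` and ``alpha * beta = k10 * k21``
    with ``k10 = CL/V1``, ``k12 = Q/V1``, ``k21 = Q/V2``.
    """
    k10 = params.cl / params.v1
    k12 = params.q / params.v1
    k21 = params.q / params.v2
    s = k10 + k12 + k21
    # The discriminant is algebraically non-negative for positive inputs;
    # clip to guard against round-off.
    disc = max((s * s) - 4.0 * k10 * k21, 0.0)
    root = np.sqrt(disc)
    alpha = 0.5 * (s + root)
    beta = 0.5 * (s - root)
    degenerate = (alpha - beta) <= _EIGEN_DEGENERACY_RTOL * alpha
    if degenerate:
        lam = 0.5 * s
        # limit of the coefficients as beta -> alpha: handled separately
        # in the evaluation routines via the t*exp(-lam t) form.
        return DispositionConstants(lam, lam, 1.0 / params.v1, 0.0, k21, True)
    coef_alpha = (alpha - k21) / (params.v1 * (alpha - beta))
    coef_beta = (k21 - beta) / (params.v1 * (alpha - beta))
    return DispositionConstants(alpha, beta, coef_alpha, coef_beta, k21, False)


def _infusion_shape(lam: float, t_in: np.ndarray, t_post: np.ndarray) -> np.ndarray:
    """(1 - exp(-lam*t_in))/lam * exp(-lam*t_post), safe at lam == 0."""
    if lam > 0.0:
        return -np.expm1(-lam * t_in) / lam * np.exp(-lam * t_post)
    return t_in * np.ones_like(t_post)


def _conc_fast(
    cl: float,
    v1: float,
    q: float,
    v2: float,
    starts: np.ndarray,
    durs: np.ndarray,
    rates: np.ndarray,
    t: np.ndarray,
) -> np.ndarray:
    """Vectorised concentration kernel over events x times.

    Internal hot path shared by :func:`concentration` and the MAP
    objective; inputs are plain floats/arrays, no validation.
    """
    if starts.size == 0:
        return np.zeros_like(t, dtype=float)
    k10 = cl / v1
    k12 = q / v1
    k21 = q / v2
    s = k10 + k12 + k21
    disc = max(s * s - 4.0 * k10 * k21, 0.0)
    root = np.sqrt(disc)
    alpha = 0.5 * (s + root)
    beta = 0.5 * (s - root)
    tt = t[None, :] - starts[:, None]
    t_in = np.clip(tt, 0.0, durs[:, None])  # time infused within each event
    t_post = np.maximum(tt - t_in, 0.0)  # time elapsed since end of infusion
    if (alpha - beta) <= _EIGEN_DEGENERACY_RTOL * alpha:
        # Critically damped limit: unit response (1/V1)*[(1 + (k21-lam) t) e^{-lam t}]
        lam = 0.5 * s
        # Convolution of the limit response with a unit-rate infusion:
        #   int_0^u e^{-lam x} dx            = (1-e^{-lam u})/lam
        #   int_0^u x e^{-lam x} dx          = (1-(1+lam u) e^{-lam u})/lam^2
        # shifted by t_post through e^{-lam t_post} factors on each primitive
        # evaluated at the infusion end; assembled via the substitution
        # x = t - s for the elapsed-time kernel.
        e_tot = np.exp(-lam * (t_in + t_post))
        e_post = np.exp(-lam * t_post)
        i0 = (e_post - e_tot) / lam
        i1 = ((t_post + 1.0 / lam) * e_post - (t_post + t_in + 1.0 / lam) * e_tot) / lam
        c = rates[:, None] / v1 * (i0 + (k21 - lam) * i1)
    else:
        ca = (alpha - k21) / (v1 * (alpha - beta))
        cb = (k21 - beta) / (v1 * (alpha - beta))
        c = rates[:, None] * (
            ca * _infusion_shape(alpha, t_in, t_post)
            + cb * _infusion_shape(beta, t_in, t_post)
        )
    return np.where(tt > 0.0, c, 0.0).sum(axis=0)


def concentration(
    params: PKParameters, regimen: DosingRegimen, t: float | Iterable[float]
) -> float | np.ndarray:
    """Plasma concentration (mg/L) at time(s) ``t`` under ``regimen``.

    Evaluates the analytic during-/post-infusion solution of the linear
    two-compartment model and superposes it over all events with
    ``start < t``.  Accepts a scalar or array of times; negative times
    raise.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise InvalidParameterError("time must be >= 0")
    starts, durs, rates = regimen.event_arrays()
    out = _conc_fast(params.cl, params.v1, params.q, params.v2, starts, durs, rates, t_arr)
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(out[0])
    return out


class InvalidIntervalError(ValueError):
    """AUC interval endpoints are not ordered t1 > t0 >= 0."""


def auc_numeric(
    params: PKParameters,
    regimen: DosingRegimen,
    t0: float,
    t1: float,
    rtol: float = 1e-9,
) -> float:
    """AUC of the concentration curve over ``[t0, t1]`` by adaptive quadrature.

    The integration interval is split at every infusion start and end
    inside it, where the integrand has derivative discontinuities, and
    each smooth piece is integrated with Gauss–Kronrod quadrature.
    Serves as the numeric oracle for steady-state AUC identities.
    """
    if not (t1 > t0 >= 0):
        raise InvalidIntervalError(f"need t1 > t0 >= 0, got t0={t0}, t1={t1}")
    if len(regimen) == 0:
        return 0.0
    breaks = {t0, t1}
    for e in regimen.events:
        for b in (e.start, e.start + e.duration):
            if t0 < b < t1:
                breaks.add(b)
    knots = sorted(breaks)
    total = 0.0
    for a, b in zip(knots, knots[1:]):
        val, _ = integrate.quad(
            lambda x: concentration(params, regimen, x), a, b, epsrel=rtol, limit=200
        )
        total += val
    return total


def auc_ss_daily(cl: float, daily_dose: float) -> float:
    """Steady-state AUC over one 24-h dosing day, mg·h/L.

    For linear kinetics the steady-state daily AUC is exactly
    ``daily_dose / CL`` regardless of the distribution volumes or the
    shape of the regimen within the day.
    """
    if cl <= 0:
        raise InvalidParameterError(f"clearance must be > 0, got {cl}")
    if daily_dose < 0:
        raise InvalidParameterError(f"daily dose must be >= 0, got {daily_dose}")
    return daily_dose / cl
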