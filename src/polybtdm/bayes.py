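"""MAP Bayesian estimation of individual PK parameters.

Given a population prior and a handful of assayed concentrations, the
maximum a posteriori (MAP) estimate minimizes

    sum_j [ (y_j - f_j)^2 / sigma_j^2 + ln sigma_j^2 ]
  + sum_k [ (ln theta_k - mu_k)^2 / omega_k^2 ]

over log-parameters, where ``f_j`` is the model-predicted concentration,
``sigma_j^2`` the residual-error variance and ``mu_k`` the log-scale
prior location (the log of the lognormal median).  Working in log space
guarantees positive estimates and turns the lognormal prior into a
Gaussian penalty.

Two weighting conventions for ``sigma_j^2`` are provided:

``"observation"`` (default)
    ``sigma_j^2`` evaluated at the observed concentration ``y_j``; the
    ``ln sigma_j^2`` term is then a constant.  With noise-free data the
    optimum reproduces the generating parameters exactly (up to prior
    pull), which makes the estimator unbiased in the small-error limit.
``"prediction"``
    Extended-least-squares: ``sigma_j^2`` at the model prediction
    ``f_j``, including the ``ln sigma_j^2`` term.  This is the textbook
    MAP objective but its log-variance term systematically pulls
    predictions down (and clearance up) when the proportional error is
    large.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import minimize

from .pkcore import DosingRegimen, PKParameters, _conc_fast
from .population import ConcentrationRecord, PopulationPKModel

__all__ = ["MAPEstimate", "map_objective", "map_estimate", "MAPNonConvergenceError"]

VarianceAt = Literal["observation", "prediction"]

#: Variance floor (mg/L)^2 guarding against a zero residual spec meeting
#: a zero prediction.
_VAR_FLOOR = 1e-12


class MAPNonConvergenceError(RuntimeError):
    """All optimizer starts failed; carries the best point found."""

    def __init__(self, message: str, best: "MAPEstimate"):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class MAPEstimate:
    """Result of one MAP fit."""

    estimated_params: PKParameters
    objective_value: float
    converged: bool
    n_observations: int


def _design_arrays(
    observations: Sequence[ConcentrationRecord],
) -> tuple[np.ndarray, np.ndarray]:
    times = np.array([r.time for r in observations], dtype=float)
    y = np.array([r.observed_conc for r in observations], dtype=float)
    return times, y


def map_objective(
    log_params: Sequence[float],
    prior: PopulationPKModel,
    observations: Sequence[ConcentrationRecord],
    regimen: DosingRegimen,
    weight: float = 1.0,
    variance_at: VarianceAt = "prediction",
) -> float:
    """-2 log-posterior (up to a constant) at absolute ``log_params``.

    ``log_params`` are logs of the absolute (not per-kg) parameters
    (ln CL, ln V1, ln Q, ln V2); the prior is the population model
    scaled to the subject's ``weight``.  Finite for all finite inputs.
    """
    lp = np.asarray(log_params, dtype=float)
    omegas = prior.omegas
    mu = prior.log_median_per_kg() + np.log(weight)
    # parameters with zero BSV carry no prior mass off the typical value;
    # treat their penalty as exactly satisfied at mu (they are fixed there
    # by map_estimate and never moved).
    free = omegas > 0
    prior_term = float(np.sum(((lp[free] - mu[free]) / omegas[free]) ** 2))
    if len(observations) == 0:
        return prior_term
    times, y = _design_arrays(observations)
    starts, durs, rates = regimen.event_arrays()
    cl, v1, q, v2 = np.exp(lp)
    f = _conc_fast(cl, v1, q, v2, starts, durs, rates, times)
    res = prior.residual
    level = y if variance_at == "observation" else f
    s2 = np.maximum(res.variance(level), _VAR_FLOOR)
    data_term = float(np.sum((y - f) ** 2 / s2 + np.log(s2)))
    return data_term + prior_term


def map_estimate(
    prior: PopulationPKModel,
    observations: Sequence[ConcentrationRecord],
    regimen: DosingRegimen,
    weight: float = 1.0,
    variance_at: VarianceAt = "observation",
    estimate_all: bool = True,
    gtol: float = 1e-8,
) -> MAPEstimate:
    """Fit one subject's parameters by minimizing :func:`map_objective`.

    Multistart quasi-Newton in log space: ln CL is started at the prior
    location and one BSV SD either side of it (three deterministic
    starts); V1, Q, V2 start at their prior locations.  With
    ``estimate_all=False`` only clearance is estimated and the other
    parameters stay fixed at the prior location (typical-value fit).
    Deterministic: identical observations give identical estimates.

    With zero observations the prior typical (arithmetic-mean)
    parameters are returned by convention.
    """
    mu = prior.log_median_per_kg() + np.log(weight)
    omegas = prior.omegas
    if len(observations) == 0:
        return MAPEstimate(
            estimated_params=prior.typical_absolute(weight),
            objective_value=0.0,
            converged=True,
            n_observations=0,
        )
    times, y = _design_arrays(observations)
    starts_arr, durs, rates = regimen.event_arrays()
    res = prior.residual
    free = (omegas > 0) if estimate_all else np.array([True, False, False, False]) & (omegas > 0)
    if not free.any():
        raise ValueError("no free parameters: all BSV terms are zero")
    idx = np.where(free)[0]
    base = mu.copy()

    if variance_at == "observation":
        s2_const = np.maximum(res.variance(y), _VAR_FLOOR)
        log_s2_const = float(np.sum(np.log(s2_const)))
    else:
        s2_const = None
        log_s2_const = 0.0

    def objective(x: np.ndarray) -> float:
        lp = base.copy()
        lp[idx] = x
        cl, v1, q, v2 = np.exp(lp)
        f = _conc_fast(cl, v1, q, v2, starts_arr, durs, rates, times)
        if s2_const is not None:
            data = np.sum((y - f) ** 2 / s2_const) + log_s2_const
        else:
            s2 = np.maximum(res.variance(f), _VAR_FLOOR)
            data = np.sum((y - f) ** 2 / s2 + np.log(s2))
        return float(data) + float(np.sum(((lp[free] - mu[free]) / omegas[free]) ** 2))

    om_cl = omegas[0] if omegas[0] > 0 else 0.3
    best = None
    best_ok = False
    for offset in (0.0, -om_cl, om_cl):
        x0 = mu[idx].copy()
        if free[0]:
            x0[np.searchsorted(idx, 0)] += offset
        result = minimize(objective, x0, method="L-BFGS-B", options={"ftol": gtol, "gtol": 1e-10})
        if best is None or result.fun < best.fun - 1e-12:
            best = result
            best_ok = bool(result.success)
    lp = base.copy()
    lp[idx] = best.x
    estimate = MAPEstimate(
        estimated_params=PKParameters.from_array(np.exp(lp)),
        objective_value=float(best.fun),
        converged=best_ok,
        n_observations=len(observations),
    )
    if not best_ok and not np.isfinite(best.fun):
        raise MAPNonConvergenceError("MAP optimization failed from all starts", estimate)
    return estimate
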