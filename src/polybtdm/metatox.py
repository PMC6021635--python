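"""Pharmacometric nephrotoxicity meta-analysis.

Published polymyxin B cohorts report nephrotoxicity on inconsistent
scales; the RIFLE acute-kidney-injury criteria (risk / injury / failure,
i.e. >=25% / >=50% / >=75% decreases in creatinine clearance) serve as
the common metric.  For each cohort a population-PK Monte-Carlo
simulation converts the reported dosing into a steady-state daily AUC
distribution; the exposure-toxicity relation is then the weighted linear
regression of the mild (>=25% CL_CR decrease) toxicity rate on the 75th
percentile of simulated ssAUC_0-24, weighted by the number of evaluated
subjects per study.  Inverting the fitted line at the maximum acceptable
mild-toxicity rate (40%) yields the upper bound of the therapeutic
window.

The packaged study table (``data/nephrotox_studies.csv``) transcribes
the published cohort summaries: doses, weights, evaluated subjects,
harmonized toxicity rates and the published simulated ssAUC percentiles.
The percentile columns are treated as input data for the regression;
their exact re-simulation depends on unpublished per-study assumptions
(see :func:`simulate_study_auc` for the package's own reconstruction).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .pkcore import InvalidParameterError
from .population import DEFAULT_MODEL, PopulationPKModel, lognormal_sigma

__all__ = [
    "StudyRecord",
    "StudySimResult",
    "WeightedRegressionResult",
    "UpperBound",
    "harmonize_grades",
    "simulate_study_auc",
    "weighted_regression",
    "unweighted_regression",
    "derive_upper_bound",
    "summarize_percentile_column",
    "load_study_table",
    "study_table_path",
    "regression_frame",
    "fit_exposure_toxicity",
]

#: Body weight (kg) assumed when a study reports absolute doses but no
#: central weight.
DEFAULT_WEIGHT_KG = 70.0


@dataclass(frozen=True)
class StudyRecord:
    """One cohort of the nephrotoxicity meta-analysis.

    ``tox_pct_ge25/50/75`` are cumulative percentages of evaluated
    subjects with at least a 25/50/75% decrease in creatinine clearance;
    ``None`` marks a grade the study does not support (distinct from 0).
    ``ssauc_p25/50/75`` are the published simulated ssAUC_0-24
    percentiles in mg·h/L (``None`` if not carried).
    """

    study: str
    n_evaluated: int
    daily_dose_mg: float
    dose_central_type: str = "mean"
    weight_kg: float | None = None
    tox_pct_ge25: float | None = None
    tox_pct_ge50: float | None = None
    tox_pct_ge75: float | None = None
    ssauc_p25: float | None = None
    ssauc_p50: float | None = None
    ssauc_p75: float | None = None

    def __post_init__(self) -> None:
        if self.n_evaluated < 1:
            raise InvalidParameterError(f"n_evaluated must be >= 1, got {self.n_evaluated}")
        grades = [self.tox_pct_ge25, self.tox_pct_ge50, self.tox_pct_ge75]
        present = [g for g in grades if g is not None]
        if any(not (0 <= g <= 100) for g in present):
            raise InvalidParameterError(f"toxicity percentages must be in [0, 100]: {grades}")
        ordered = [g for g in grades if g is not None]
        if any(b > a + 1e-9 for a, b in zip(ordered, ordered[1:])):
            raise InvalidParameterError(
                f"cumulative grades must be non-increasing, got {grades}"
            )
        pcts = [self.ssauc_p25, self.ssauc_p50, self.ssauc_p75]
        known = [p for p in pcts if p is not None]
        if any(b < a - 1e-9 for a, b in zip(known, known[1:])):
            raise InvalidParameterError(f"ssAUC percentiles must be ordered, got {pcts}")


class StudySimResult(NamedTuple):
    """Simulated ssAUC_0-24 quartiles of one study, mg·h/L."""

    study: str
    ssauc_p25: float
    ssauc_p50: float
    ssauc_p75: float


def harmonize_grades(
    n_evaluated: int,
    risk: int | None = None,
    injury: int | None = None,
    failure: int | None = None,
    injury_or_failure: int | None = None,
) -> tuple[float | None, float | None, float | None]:
    """Cumulative RIFLE grade percentages from exclusive category counts.

    ``risk``, ``injury`` and ``failure`` are counts of subjects whose
    *worst* grade was the respective RIFLE category; ``injury_or_failure``
    covers studies that pool the two upper grades.  A subject in a higher
    grade counts in every lower cumulative grade.  Grades that cannot be
    derived from the reported categories are returned as ``None`` (absent,
    not zero) and the corresponding study is dropped listwise from any
    regression on that grade.
    """
    if n_evaluated < 1:
        raise InvalidParameterError("n_evaluated must be >= 1")
    counts = [c for c in (risk, injury, failure, injury_or_failure) if c is not None]
    if any(c < 0 for c in counts):
        raise InvalidParameterError("category counts must be >= 0")
    if sum(counts) > n_evaluated:
        raise InvalidParameterError(
            f"category counts sum to {sum(counts)} > n_evaluated {n_evaluated}"
        )
    ge75_count = failure
    if injury is not None and failure is not None:
        ge50_count = injury + failure
    elif injury_or_failure is not None:
        ge50_count = injury_or_failure
    else:
        ge50_count = None
    ge25_count = risk + ge50_count if (risk is not None and ge50_count is not None) else None
    to_pct = lambda c: None if c is None else 100.0 * c / n_evaluated
    return to_pct(ge25_count), to_pct(ge50_count), to_pct(ge75_count)


def simulate_study_auc(
    study: StudyRecord,
    model: PopulationPKModel = DEFAULT_MODEL,
    n: int = 10000,
    assumed_weight: float = DEFAULT_WEIGHT_KG,
    rng: np.random.Generator | int | None = None,
) -> StudySimResult:
    """Reconstruct a study's ssAUC_0-24 quartiles by Monte-Carlo simulation.

    Clearances are drawn from the population model (lognormal,
    arithmetic-mean-preserving); the study's central daily dose in
    mg/day is divided by absolute clearance (per-kg clearance times the
    study's central weight, or ``assumed_weight`` when unreported).
    The dose is held fixed at its central value: the spread of the
    distribution comes from between-subject clearance variability.
    """
    if study.daily_dose_mg is None or not np.isfinite(study.daily_dose_mg):
        raise InvalidParameterError(f"study {study.study} has no usable dose")
    rng = np.random.default_rng(rng)
    weight = study.weight_kg if study.weight_kg is not None else assumed_weight
    cl_typ = model.typical_per_kg.cl * weight
    omega = lognormal_sigma(model.bsv_cv[0])
    cl = np.exp(np.log(cl_typ) - 0.5 * omega**2 + omega * rng.standard_normal(n))
    auc = study.daily_dose_mg / cl
    p25, p50, p75 = np.percentile(auc, [25, 50, 75])
    return StudySimResult(study.study, float(p25), float(p50), float(p75))


@dataclass(frozen=True)
class WeightedRegressionResult:
    """Weighted least-squares exposure-toxicity line.

    ``y = intercept + slope * x`` with y the mild-toxicity rate in % and
    x an ssAUC_0-24 percentile in mg·h/L.  The p-value is a two-sided t
    test on the slope with ``n_studies - 2`` degrees of freedom, scale
    estimated from the weighted residuals.  Invariant to rescaling all
    weights by a common factor.
    """

    slope: float
    intercept: float
    slope_se: float
    t_statistic: float
    p_value: float
    n_studies: int
    weights: tuple[float, ...]

    def predict(self, x: float | np.ndarray) -> float | np.ndarray:
        return self.intercept + self.slope * np.asarray(x)


def weighted_regression(
    x: Sequence[float], y: Sequence[float], w: Sequence[float]
) -> WeightedRegressionResult:
    """WLS of toxicity rate on exposure, weighted by study size."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if x.size != y.size or x.size != w.size:
        raise InvalidParameterError("x, y, w must have equal length")
    if x.size < 3:
        raise InvalidParameterError(f"need >= 3 studies, got {x.size}")
    if np.any(w < 0) or w.sum() <= 0:
        raise InvalidParameterError("weights must be >= 0 with positive total")
    fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    return WeightedRegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_se=float(fit.bse[1]),
        t_statistic=float(fit.tvalues[1]),
        p_value=float(fit.pvalues[1]),
        n_studies=int(x.size),
        weights=tuple(float(v) for v in w),
    )


def unweighted_regression(x: Sequence[float], y: Sequence[float]) -> WeightedRegressionResult:
    """Ordinary least-squares comparator (all studies weighted equally)."""
    x = np.asarray(x, dtype=float)
    return weighted_regression(x, y, np.ones(x.size))


class UpperBound(NamedTuple):
    """Raw and clinically rounded window upper bound, mg·h/L."""

    raw: float
    rounded: float


def derive_upper_bound(
    fit: WeightedRegressionResult, max_acceptable_rate: float = 40.0, rounding_step: float = 10.0
) -> UpperBound:
    """Exposure at which the fitted mild-toxicity rate hits the cap.

    Inverts the regression line: ``x = (rate - intercept)/slope``.  With
    the published fit and a 40% cap this is ~99.3 mg·h/L, clinically
    rounded to 100.
    """
    if fit.slope <= 0:
        raise InvalidParameterError(
            f"no finite bound: slope must be > 0, got {fit.slope}"
        )
    raw = (max_acceptable_rate - fit.intercept) / fit.slope
    rounded = round(raw / rounding_step) * rounding_step
    return UpperBound(float(raw), float(rounded))


def summarize_percentile_column(
    results: Sequence[StudySimResult] | Sequence[StudyRecord], which: int = 75
) -> tuple[float, float, float]:
    """Median, min and max of one ssAUC percentile column across studies.

    ``which`` is 25, 50 or 75.  The median of an even count is the mean
    of the two middle values.
    """
    attr = {25: "ssauc_p25", 50: "ssauc_p50", 75: "ssauc_p75"}[which]
    vals = np.array([getattr(r, attr) for r in results if getattr(r, attr) is not None])
    if vals.size == 0:
        raise InvalidParameterError("no values to summarize")
    return float(np.median(vals)), float(vals.min()), float(vals.max())


def study_table_path() -> str:
    """Filesystem path of the packaged study table CSV."""
    return str(importlib.resources.files("polybtdm.data") / "nephrotox_studies.csv")


def load_study_table(path: str | None = None) -> list[StudyRecord]:
    """Load the packaged (or a user-supplied) meta-analysis study table."""
    df = pd.read_csv(path if path is not None else study_table_path())
    records = []
    opt = lambda v: None if pd.isna(v) else float(v)
    for _, row in df.iterrows():
        records.append(
            StudyRecord(
                study=str(row["study"]),
                n_evaluated=int(row["n_evaluated"]),
                daily_dose_mg=float(row["daily_dose_mg"]),
                dose_central_type=str(row["dose_central_type"]),
                weight_kg=opt(row.get("weight_kg")),
                tox_pct_ge25=opt(row.get("tox_pct_ge25")),
                tox_pct_ge50=opt(row.get("tox_pct_ge50")),
                tox_pct_ge75=opt(row.get("tox_pct_ge75")),
                ssauc_p25=opt(row.get("ssauc_p25")),
                ssauc_p50=opt(row.get("ssauc_p50")),
                ssauc_p75=opt(row.get("ssauc_p75")),
            )
        )
    return records


def regression_frame(
    studies: Sequence[StudyRecord], grade: int = 25, percentile: int = 75
) -> pd.DataFrame:
    """Listwise-complete (study, x, y, w) frame for the grade regression."""
    g_attr = {25: "tox_pct_ge25", 50: "tox_pct_ge50", 75: "tox_pct_ge75"}[grade]
    p_attr = {25: "ssauc_p25", 50: "ssauc_p50", 75: "ssauc_p75"}[percentile]
    rows = [
        {
            "study": s.study,
            "x": getattr(s, p_attr),
            "y": getattr(s, g_attr),
            "w": float(s.n_evaluated),
        }
        for s in studies
        if getattr(s, g_attr) is not None and getattr(s, p_attr) is not None
    ]
    return pd.DataFrame(rows)


def fit_exposure_toxicity(
    studies: Sequence[StudyRecord] | None = None,
    grade: int = 25,
    percentile: int = 75,
    weighted: bool = True,
) -> WeightedRegressionResult:
    """The headline meta-regression on the packaged (or given) study table."""
    if studies is None:
        studies = load_study_table()
    frame = regression_frame(studies, grade=grade, percentile=percentile)
    if weighted:
        return weighted_regression(frame["x"], frame["y"], frame["w"])
    return unweighted_regression(frame["x"], frame["y"])
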