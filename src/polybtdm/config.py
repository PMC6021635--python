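"""Configuration loading, validation and file I/O.

A run is described by one YAML file with four blocks — population model,
dosing regimen, target window and simulation settings — plus a strategy
list.  Keys embed their units (``cl_L_h_kg``, ``interval_h``): unit
mistakes are the dominant failure mode in dosing software, so they are
spelled out rather than implied.  Unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Sequence

import importlib.resources

import numpy as np
import pandas as pd
import yaml

from .control_sim import SamplingStrategy, traditional_regimen
from .dosing import TargetWindow
from .pkcore import DosingRegimen, PKParameters, SamplingSchedule
from .population import PopulationPKModel, ResidualErrorSpec, sample_subjects, simulate_observations

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "dump_config",
    "default_config_path",
    "config_hash",
    "read_concentration_csv",
    "write_concentration_csv",
    "make_fixtures",
]


class ConfigError(ValueError):
    """A configuration file violates the schema; names the offending key."""


_POPULATION_KEYS = {
    "cl_L_h_kg",
    "cl_bsv_cv",
    "v1_L_kg",
    "v1_bsv_cv",
    "q_L_h_kg",
    "q_bsv_cv",
    "v2_L_kg",
    "v2_bsv_cv",
    "residual_proportional_cv",
    "residual_additive_sd_mg_L",
}
_REGIMEN_KEYS = {
    "loading_dose_mg_kg",
    "loading_duration_h",
    "maintenance_dose_mg_kg",
    "maintenance_duration_h",
    "interval_h",
}
_WINDOW_KEYS = {"lower_mg_h_L", "midpoint_mg_h_L", "upper_mg_h_L"}
_SIMULATION_KEYS = {"n_subjects", "seed"}


@dataclass(frozen=True)
class RunConfig:
    """A fully validated run configuration."""

    model: PopulationPKModel
    window: TargetWindow
    strategies: tuple[SamplingStrategy, ...]
    loading_dose_mg_kg: float
    loading_duration_h: float
    maintenance_dose_mg_kg: float
    maintenance_duration_h: float
    interval_h: float
    n_subjects: int
    seed: int

    def regimen(self, weight: float = 1.0, n_doses: int = 5) -> DosingRegimen:
        return traditional_regimen(
            weight=weight,
            loading_per_kg=self.loading_dose_mg_kg,
            loading_duration=self.loading_duration_h,
            maintenance_per_kg=self.maintenance_dose_mg_kg,
            maintenance_duration=self.maintenance_duration_h,
            interval=self.interval_h,
            n_doses=n_doses,
        )


def _check_keys(block: dict, allowed: set[str], name: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in '{name}' block: {sorted(unknown)}")
    missing = allowed - set(block)
    if missing:
        raise ConfigError(f"missing key(s) in '{name}' block: {sorted(missing)}")


def _parse(raw: dict[str, Any]) -> RunConfig:
    top_allowed = {"population", "regimen", "window", "simulation", "strategies"}
    _check_keys(raw, top_allowed, "top-level")
    pop = raw["population"]
    _check_keys(pop, _POPULATION_KEYS, "population")
    reg = raw["regimen"]
    _check_keys(reg, _REGIMEN_KEYS, "regimen")
    win = raw["window"]
    _check_keys(win, _WINDOW_KEYS, "window")
    simb = raw["simulation"]
    _check_keys(simb, _SIMULATION_KEYS, "simulation")
    try:
        typical = PKParameters(
            cl=float(pop["cl_L_h_kg"]),
            v1=float(pop["v1_L_kg"]),
            q=float(pop["q_L_h_kg"]),
            v2=float(pop["v2_L_kg"]),
        )
        model = PopulationPKModel(
            typical_per_kg=typical,
            bsv_cv=(
                float(pop["cl_bsv_cv"]),
                float(pop["v1_bsv_cv"]),
                float(pop["q_bsv_cv"]),
                float(pop["v2_bsv_cv"]),
            ),
            residual=ResidualErrorSpec(
                proportional_cv=float(pop["residual_proportional_cv"]),
                additive_sd=float(pop["residual_additive_sd_mg_L"]),
            ),
        )
        window = TargetWindow(
            lower=float(win["lower_mg_h_L"]),
            upper=float(win["upper_mg_h_L"]),
            midpoint=float(win["midpoint_mg_h_L"]),
        )
        strategies = tuple(
            SamplingStrategy(
                label=str(s["label"]),
                schedule=SamplingSchedule(tuple(float(t) for t in s["times_h"])),
            )
            for s in raw["strategies"]
        )
    except (ValueError, KeyError, TypeError) as exc:
        raise ConfigError(f"invalid configuration value: {exc}") from exc
    n_subjects = int(simb["n_subjects"])
    if n_subjects < 1:
        raise ConfigError(f"simulation.n_subjects must be >= 1, got {n_subjects}")
    return RunConfig(
        model=model,
        window=window,
        strategies=strategies,
        loading_dose_mg_kg=float(reg["loading_dose_mg_kg"]),
        loading_duration_h=float(reg["loading_duration_h"]),
        maintenance_dose_mg_kg=float(reg["maintenance_dose_mg_kg"]),
        maintenance_duration_h=float(reg["maintenance_duration_h"]),
        interval_h=float(reg["interval_h"]),
        n_subjects=n_subjects,
        seed=int(simb["seed"]),
    )


def default_config_path() -> str:
    return str(importlib.resources.files("polybtdm.data") / "default_config.yaml")


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML run configuration (default if ``path`` is None)."""
    p = Path(path) if path is not None else Path(default_config_path())
    with open(p) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    return _parse(raw)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a RunConfig back to YAML; load(dump(load(x))) is identity."""
    m = cfg.model
    raw = {
        "population": {
            "cl_L_h_kg": m.typical_per_kg.cl,
            "cl_bsv_cv": m.bsv_cv[0],
            "v1_L_kg": m.typical_per_kg.v1,
            "v1_bsv_cv": m.bsv_cv[1],
            "q_L_h_kg": m.typical_per_kg.q,
            "q_bsv_cv": m.bsv_cv[2],
            "v2_L_kg": m.typical_per_kg.v2,
            "v2_bsv_cv": m.bsv_cv[3],
            "residual_proportional_cv": m.residual.proportional_cv,
            "residual_additive_sd_mg_L": m.residual.additive_sd,
        },
        "regimen": {
            "loading_dose_mg_kg": cfg.loading_dose_mg_kg,
            "loading_duration_h": cfg.loading_duration_h,
            "maintenance_dose_mg_kg": cfg.maintenance_dose_mg_kg,
            "maintenance_duration_h": cfg.maintenance_duration_h,
            "interval_h": cfg.interval_h,
        },
        "window": {
            "lower_mg_h_L": cfg.window.lower,
            "midpoint_mg_h_L": cfg.window.midpoint,
            "upper_mg_h_L": cfg.window.upper,
        },
        "simulation": {"n_subjects": cfg.n_subjects, "seed": cfg.seed},
        "strategies": [
            {"label": s.label, "times_h": list(s.schedule.times)} for s in cfg.strategies
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash of a configuration, embedded in output metadata."""
    m = cfg.model
    payload = json.dumps(
        {
            "typical": list(m.typical_per_kg.as_array()),
            "bsv": list(m.bsv_cv),
            "residual": [m.residual.proportional_cv, m.residual.additive_sd],
            "window": [cfg.window.lower, cfg.window.midpoint, cfg.window.upper],
            "regimen": [
                cfg.loading_dose_mg_kg,
                cfg.loading_duration_h,
                cfg.maintenance_dose_mg_kg,
                cfg.maintenance_duration_h,
                cfg.interval_h,
            ],
            "strategies": [[s.label, list(s.schedule.times)] for s in cfg.strategies],
            "n": cfg.n_subjects,
            "seed": cfg.seed,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# concentration-record CSV I/O


def write_concentration_csv(records, path: str | Path, weights: dict | None = None) -> None:
    """Write ConcentrationRecords as subject_id,time_h,conc_mg_L[,weight_kg]."""
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "time_h": r.time, "conc_mg_L": r.observed_conc}
        if weights is not None:
            row["weight_kg"] = weights[r.subject_id]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_concentration_csv(path: str | Path) -> pd.DataFrame:
    """Read a concentration CSV, validating the mandatory header."""
    df = pd.read_csv(path)
    required = {"subject_id", "time_h", "conc_mg_L"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"concentration CSV missing column(s): {sorted(missing)}")
    if (df["time_h"] < 0).any():
        raise ConfigError("concentration CSV has negative times")
    if (df["conc_mg_L"] < 0).any():
        raise ConfigError("concentration CSV has negative concentrations")
    return df


def make_fixtures(out_dir: str | Path, seed: int = 0, n_subjects: int = 6) -> dict[str, Path]:
    """Write the demo fixture files into ``out_dir``.

    Produces the meta-analysis study table (a copy of the packaged
    transcription), the sampling-strategy definitions, and a small
    simulated concentration CSV (fixed seed) for estimator demos.
    Regeneration with the same seed is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = load_config()
    paths: dict[str, Path] = {}

    studies = out / "nephrotox_studies.csv"
    studies.write_bytes(Path(default_study_table()).read_bytes())
    paths["studies"] = studies

    strat = out / "sampling_strategies.csv"
    pd.DataFrame(
        [
            {"label": s.label, "n_samples": s.n_samples, "times_h": " ".join(map(str, s.schedule.times))}
            for s in cfg.strategies
        ]
    ).to_csv(strat, index=False)
    paths["strategies"] = strat

    conc = out / "demo_concentrations.csv"
    rng_master = np.random.SeedSequence(seed)
    subj_ss, noise_ss = (
        np.random.SeedSequence(entropy=rng_master.entropy, spawn_key=(0,)),
        np.random.SeedSequence(entropy=rng_master.entropy, spawn_key=(1,)),
    )
    weight = 70.0
    subjects = sample_subjects(
        cfg.model, n_subjects, weight=weight, rng=np.random.default_rng(subj_ss)
    )
    regimen = cfg.regimen(weight=weight)
    schedule = SamplingSchedule((2.0, 4.0, 12.0, 24.0))
    records = []
    wmap = {}
    for s, child in zip(subjects, noise_ss.spawn(n_subjects)):
        records.extend(
            simulate_observations(
                s, regimen, schedule, cfg.model.residual, rng=np.random.default_rng(child)
            )
        )
        wmap[s.id] = s.weight
    write_concentration_csv(records, conc, weights=wmap)
    paths["concentrations"] = conc
    return paths


def default_study_table() -> str:
    from .metatox import study_table_path

    return study_table_path()
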