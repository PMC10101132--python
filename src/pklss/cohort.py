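"""Virtual patient population for severe hemophilia A.

Generates demographics (age, body weight, BMI, fat-free mass) with a
hierarchical sampler calibrated to the reference cohort summaries, draws
each patient's true random effects from the population model's IIV
distribution, and assigns weight-based doses rounded to vial size.

All patients are male (severe hemophilia A is X-linked). Children are
defined as age < 12 years; ties at exactly 12.0 fall in the adult stratum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .popmodel import ConfigError, IndividualParameters, PopulationPKModel, individual_parameters

__all__ = [
    "Demographics",
    "VirtualPatient",
    "compute_ffm",
    "sample_population",
    "draw_etas",
    "assign_dose",
    "build_cohort",
    "population_to_dataframe",
    "load_demographics_config",
    "default_demographics_config",
]

CHILD_AGE_CUTOFF = 12.0


@dataclass(frozen=True)
class Demographics:
    """Covariate set of one virtual patient."""

    patient_id: int
    age: float          # years
    body_weight: float  # kg
    bmi: float          # kg/m^2
    ffm: float          # kg

    @property
    def is_child(self) -> bool:
        return self.age < CHILD_AGE_CUTOFF

    @property
    def covariates(self) -> dict[str, float]:
        return {
            "age": self.age,
            "weight": self.body_weight,
            "bmi": self.bmi,
            "ffm": self.ffm,
        }


@dataclass(frozen=True)
class VirtualPatient:
    """Demographics plus simulation truth: random effects, parameters, dose."""

    demographics: Demographics
    eta_true: np.ndarray
    params_true: IndividualParameters
    dose_iu: float


def compute_ffm(age: float, weight: float, bmi: float) -> float:
    """Fat-free mass (kg) for a male from age, body weight and BMI.

    Al-Sallami maturation form: an adult male fat-free mass term
    9270*W / (6680 + 216*BMI) scaled by a sigmoidal age maturation
    0.88 + 0.12 / (1 + (age/13.4)^-12.7), valid across children and adults.
    """
    age = np.asarray(age, dtype=float)
    weight = np.asarray(weight, dtype=float)
    bmi = np.asarray(bmi, dtype=float)
    if np.any(age <= 0) or np.any(weight <= 0) or np.any(bmi <= 0):
        raise ValueError("age, weight and bmi must be positive")
    maturation = 0.88 + 0.12 / (1.0 + (age / 13.4) ** (-12.7))
    ffm = maturation * 9270.0 * weight / (6680.0 + 216.0 * bmi)
    return float(ffm) if ffm.ndim == 0 else ffm


def default_demographics_config() -> dict:
    with resources.files("pklss.configs").joinpath("demographics.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_demographics_config(path: str | Path | dict | None = None) -> dict:
    if path is None:
        return default_demographics_config()
    if isinstance(path, dict):
        return path
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"demographics config not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"demographics config {path} is not a mapping")
    return cfg


def _lognormal_around_median(
    rng: np.random.Generator, median: np.ndarray, sigma_log: np.ndarray,
    lo: float, hi: float,
) -> np.ndarray:
    """Log-normal draws with given median, re-drawn until inside [lo, hi]."""
    n = len(median)
    out = np.empty(n)
    todo = np.arange(n)
    for _ in range(1000):
        draw = median[todo] * np.exp(sigma_log[todo] * rng.standard_normal(len(todo)))
        ok = (draw >= lo) & (draw <= hi)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
        if len(todo) == 0:
            return out
    raise RuntimeError("rejection sampling failed to converge; check bounds")


def sample_population(
    n: int, seed: int, config: dict | str | Path | None = None
) -> list[Demographics]:
    """Draw ``n`` virtual patients' demographics, reproducibly for a seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = load_demographics_config(config)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    p_child = float(cfg["child_fraction"])
    if not (0.0 <= p_child < 1.0):
        raise ConfigError("child_fraction must be in [0, 1)")
    is_child = rng.random(n) < p_child

    acfg = cfg["age"]
    age = np.empty(n)
    nc = int(is_child.sum())
    # children: scaled Beta on [min, 12)
    age[is_child] = float(acfg["min"]) + (CHILD_AGE_CUTOFF - float(acfg["min"])) * rng.beta(
        float(acfg["child"]["beta_a"]), float(acfg["child"]["beta_b"]), nc
    )
    age[is_child] = np.minimum(age[is_child], CHILD_AGE_CUTOFF - 1e-3)
    # adults: truncated log-normal on [12, max]
    na = n - nc
    med = float(acfg["adult"]["median"])
    sig = float(acfg["adult"]["sigma_log"])
    adult_ages = np.empty(na)
    todo = np.arange(na)
    while len(todo):
        draw = med * np.exp(sig * rng.standard_normal(len(todo)))
        ok = (draw >= CHILD_AGE_CUTOFF) & (draw <= float(acfg["max"]))
        adult_ages[todo[ok]] = draw[ok]
        todo = todo[~ok]
    age[~is_child] = adult_ages

    wcfg = cfg["weight"]
    knots = wcfg["median_knots"]
    w_median = np.exp(
        np.interp(age, np.asarray(knots["age"], float), np.log(np.asarray(knots["weight"], float)))
    )
    w_sigma = np.where(is_child, float(wcfg["sigma_log_child"]), float(wcfg["sigma_log_adult"]))
    weight = _lognormal_around_median(rng, w_median, w_sigma, float(wcfg["min"]), float(wcfg["max"]))

    bcfg = cfg["bmi"]
    bknots = bcfg["median_knots"]
    b_median = np.exp(
        np.interp(age, np.asarray(bknots["age"], float), np.log(np.asarray(bknots["bmi"], float)))
    )
    b_sigma = np.where(is_child, float(bcfg["sigma_log_child"]), float(bcfg["sigma_log_adult"]))
    bmi = _lognormal_around_median(rng, b_median, b_sigma, float(bcfg["min"]), float(bcfg["max"]))

    ffm = compute_ffm(age, weight, bmi)
    return [
        Demographics(
            patient_id=i,
            age=float(age[i]),
            body_weight=float(weight[i]),
            bmi=float(bmi[i]),
            ffm=float(ffm[i]),
        )
        for i in range(n)
    ]


def draw_etas(model: PopulationPKModel, n: int, seed: int) -> np.ndarray:
    """Draw n rows of true random effects eta ~ MVN(0, omega)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    k = model.n_eta
    if k == 0:
        return np.zeros((n, 0))
    if not np.any(model.omega):
        return np.zeros((n, k))
    chol = np.linalg.cholesky(model.omega + 1e-300 * np.eye(k))
    return rng.standard_normal((n, k)) @ chol.T


def assign_dose(weight: float, iu_per_kg: float, increment: float = 250.0) -> float:
    """Weight-based dose rounded to the nearest vial-size multiple (half up)."""
    if weight <= 0:
        raise ValueError("weight must be positive")
    exact = weight * iu_per_kg
    return increment * math.floor(exact / increment + 0.5)


def build_cohort(
    model: PopulationPKModel,
    demographics: list[Demographics],
    iu_per_kg: float,
    seed: int,
    dose_increment: float = 250.0,
) -> list[VirtualPatient]:
    """Attach true random effects, true parameters and a rounded dose."""
    etas = draw_etas(model, len(demographics), seed)
    patients = []
    for demog, eta in zip(demographics, etas):
        params = individual_parameters(model, demog.covariates, eta)
        patients.append(
            VirtualPatient(
                demographics=demog,
                eta_true=eta,
                params_true=params,
                dose_iu=assign_dose(demog.body_weight, iu_per_kg, dose_increment),
            )
        )
    return patients


def population_to_dataframe(patients: list[VirtualPatient]) -> pd.DataFrame:
    rows = []
    for p in patients:
        d = p.demographics
        rows.append(
            {
                "patient_id": d.patient_id,
                "age": d.age,
                "weight": d.body_weight,
                "bmi": d.bmi,
                "ffm": d.ffm,
                "stratum": "child" if d.is_child else "adult",
                "dose_iu": p.dose_iu,
                "CL": p.params_true.CL,
                "V1": p.params_true.V1,
                "Q": p.params_true.Q,
                "V2": p.params_true.V2,
                "Vss": p.params_true.Vss,
                "t_half": p.params_true.t_half,
            }
        )
    return pd.DataFrame(rows)
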