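"""Closed-form two-compartment IV-bolus kinetics and observation simulation.

Concentrations follow the bi-exponential C(t) = D*(A e^{-alpha t} + B e^{-beta t});
at steady state under q-tau dosing each exponential term carries the
accumulation factor 1/(1 - e^{-lambda tau}). Evaluating the steady-state
expression at t > tau corresponds to withholding the next dose after the
profiled one, which is how post-interval samples (e.g. 96 h under q72h)
are obtained. Patients have no endogenous FVIII baseline.

Observations are generated at realized times drawn uniformly within each
design window, perturbed by combined proportional + additive residual error,
floored at zero, and censored below the LLOQ (strictly below).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import VirtualPatient
from .designs import SamplingDesign
from .popmodel import IndividualParameters, PopulationPKModel

__all__ = [
    "DoseRegimen",
    "Observation",
    "ObservationSet",
    "conc_single_dose",
    "conc_steady_state",
    "realize_times",
    "add_residual_error",
    "censor",
    "simulate_observations",
    "bql_fraction",
    "nonmem_dataset",
]


@dataclass(frozen=True)
class DoseRegimen:
    dose_iu: float
    interval: float  # tau, h
    steady_state: bool = True

    def __post_init__(self) -> None:
        if self.dose_iu < 0:
            raise ValueError("dose_iu must be >= 0")
        if self.interval <= 0:
            raise ValueError("interval must be > 0")


@dataclass(frozen=True)
class Observation:
    nominal_time: float
    realized_time: float
    conc_observed: float | None  # None when censored
    bql: bool
    lloq: float


@dataclass(frozen=True)
class ObservationSet:
    patient_id: int
    regimen: DoseRegimen
    observations: tuple[Observation, ...]

    def __post_init__(self) -> None:
        times = [o.realized_time for o in self.observations]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("observation times must be strictly increasing")


def conc_single_dose(params: IndividualParameters, dose: float, t) -> np.ndarray | float:
    """Concentration (IU/ml) at time t (h) after a single IV bolus."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    c = dose * (params.A * np.exp(-params.alpha * t) + params.B * np.exp(-params.beta * t))
    return float(c) if c.ndim == 0 else c


def conc_steady_state(
    params: IndividualParameters, regimen: DoseRegimen, t_after_dose
) -> np.ndarray | float:
    """Steady-state concentration t_after_dose h after the profiled dose.

    Valid for t_after_dose > tau: no further dose is given after the
    profiled one, so the steady-state curve simply continues to decay.
    """
    t = np.asarray(t_after_dose, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    if not regimen.steady_state:
        return conc_single_dose(params, regimen.dose_iu, t_after_dose)
    tau = regimen.interval
    acc_a = 1.0 / -math.expm1(-params.alpha * tau)
    acc_b = 1.0 / -math.expm1(-params.beta * tau)
    c = regimen.dose_iu * (
        params.A * acc_a * np.exp(-params.alpha * t)
        + params.B * acc_b * np.exp(-params.beta * t)
    )
    return float(c) if c.ndim == 0 else c


def realize_times(design: SamplingDesign, rng: np.random.Generator) -> np.ndarray:
    """Draw realized sampling times uniformly within each design window, sorted."""
    times: list[float] = []
    for spec in design.sample_specs:
        lo, hi = spec.window
        for _ in range(spec.multiplicity):
            times.append(float(rng.uniform(lo, hi)) if hi > lo else lo)
    return np.sort(np.asarray(times))


def add_residual_error(
    true_conc, model: PopulationPKModel, rng: np.random.Generator
) -> np.ndarray | float:
    """y = f*(1 + eps_prop) + eps_add, floored at 0."""
    f = np.asarray(true_conc, dtype=float)
    if np.any(f < 0):
        raise ValueError("true concentration must be >= 0")
    y = (
        f * (1.0 + model.sigma_prop * rng.standard_normal(f.shape))
        + model.sigma_add * rng.standard_normal(f.shape)
    )
    y = np.maximum(y, 0.0)
    return float(y) if y.ndim == 0 else y


def censor(noisy_conc: float, lloq: float, nominal_time: float = np.nan,
           realized_time: float = np.nan) -> Observation:
    """Mask values strictly below the LLOQ as BQL."""
    bql = noisy_conc < lloq
    return Observation(
        nominal_time=nominal_time,
        realized_time=realized_time,
        conc_observed=None if bql else float(noisy_conc),
        bql=bool(bql),
        lloq=lloq,
    )


def simulate_observations(
    patient: VirtualPatient,
    design: SamplingDesign,
    model: PopulationPKModel,
    regimen: DoseRegimen,
    rng: np.random.Generator,
) -> ObservationSet:
    """Simulate one patient's observed (noisy, censored) design samples."""
    nominal: list[float] = list(design.nominal_times)
    times = realize_times(design, rng)
    f = conc_steady_state(patient.params_true, regimen, times)
    y = add_residual_error(f, model, rng)
    obs = tuple(
        censor(y[i], model.lloq, nominal_time=nominal[i], realized_time=float(times[i]))
        for i in range(len(times))
    )
    return ObservationSet(patient.demographics.patient_id, regimen, obs)


def bql_fraction(
    patients: list[VirtualPatient],
    model: PopulationPKModel,
    iu_per_kg: float,
    interval: float,
    window: tuple[float, float],
    seed: int,
) -> dict[str, float]:
    """Percent of patients whose one observation in the window is BQL, per stratum.

    Each patient contributes a single sample at a uniform random time within
    the window, with residual error, judged against the model LLOQ.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    n = len(patients)
    times = rng.uniform(window[0], window[1], n)
    flags = np.empty(n, dtype=bool)
    child = np.empty(n, dtype=bool)
    for i, p in enumerate(patients):
        regimen = DoseRegimen(p.dose_iu, interval)
        f = conc_steady_state(p.params_true, regimen, times[i])
        y = add_residual_error(f, model, rng)
        flags[i] = y < model.lloq
        child[i] = p.demographics.is_child
    out = {"all": 100.0 * flags.mean()}
    for name, mask in (("adult", ~child), ("child", child)):
        out[name] = 100.0 * flags[mask].mean() if mask.any() else float("nan")
    return out


def nonmem_dataset(
    patients: list[VirtualPatient],
    obs_sets: list[ObservationSet],
) -> pd.DataFrame:
    """Rectangular NONMEM-style dataset (ID, TIME, AMT, DV, MDV, EVID, BLQ, SS, II).

    One steady-state dose record per patient at time 0 followed by the
    observation records; BQL records carry DV at the LLOQ with BLQ=1.
    """
    rows = []
    by_id = {p.demographics.patient_id: p for p in patients}
    for oset in obs_sets:
        p = by_id[oset.patient_id]
        rows.append(
            {
                "ID": oset.patient_id, "TIME": 0.0, "AMT": p.dose_iu, "DV": ".",
                "MDV": 1, "EVID": 1, "BLQ": 0, "SS": 1, "II": oset.regimen.interval,
            }
        )
        for o in oset.observations:
            rows.append(
                {
                    "ID": oset.patient_id, "TIME": round(o.realized_time, 4), "AMT": 0.0,
                    "DV": o.lloq if o.bql else round(o.conc_observed, 6),
                    "MDV": 0, "EVID": 0, "BLQ": int(o.bql), "SS": 0, "II": 0.0,
                }
            )
    return pd.DataFrame(rows)
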