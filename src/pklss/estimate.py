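"""Bayesian MAP (empirical Bayes) estimation of individual PK from sparse data.

Minimizes -2 log posterior over the individual random effects eta:

    sum_quantified [ log(2*pi*g^2) + (y - f)^2 / g^2 ]
  + sum_BQL       [ -2 * log Phi((LLOQ - f) / g) ]          (M3 likelihood)
  + eta' Omega^-1 eta + log|2*pi*Omega|                      (population prior)

where f is the steady-state model prediction at the realized sampling time
and g^2 = f^2 sigma_prop^2 + sigma_add^2 is the residual variance evaluated
at the prediction (standard M3). A below-LLOQ observation contributes the
probability mass below the quantification limit; with no BQL samples the
objective reduces to the ordinary Gaussian -2LL plus the prior penalty.

The optimizer is quasi-Newton (L-BFGS-B) over the 2-4 dimensional eta with
multi-start (eta = 0 plus jittered starts); the best objective is kept and
non-convergence is flagged, never fatal. The objective closure is written
with scalar math on purpose: it is evaluated tens of millions of times in a
full design evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from ._bfgs import minimize_bfgs_small

from .popmodel import IndividualParameters, PopulationPKModel, individual_parameters
from .simulate import DoseRegimen, Observation, ObservationSet, conc_steady_state

__all__ = ["MAPResult", "neg2_log_posterior", "make_objective", "map_estimate", "predict_trough"]

_INV_SQRT2 = 1.0 / math.sqrt(2.0)
_LOG_2PI = math.log(2.0 * math.pi)


def _log_phi(x: float) -> float:
    """log of the standard normal CDF, stable for large negative x."""
    if x > -10.0:
        return math.log(0.5 * math.erfc(-x * _INV_SQRT2))
    xx = x * x
    return -0.5 * xx - 0.5 * _LOG_2PI - math.log(-x) + math.log1p(-1.0 / xx + 3.0 / (xx * xx))


@dataclass(frozen=True)
class MAPResult:
    patient_id: int
    design_id: str
    eta_hat: np.ndarray
    params_hat: IndividualParameters
    predicted_trough: float
    converged: bool
    objective_value: float
    n_bql_used: int


def _as_observation_list(observations) -> list[Observation]:
    if isinstance(observations, ObservationSet):
        return list(observations.observations)
    return list(observations)


def make_objective(
    model: PopulationPKModel,
    covariates,
    regimen: DoseRegimen,
    observations,
) -> Callable[[Sequence[float]], float]:
    """Build the -2 log posterior closure over eta for one patient.

    Only models with IIV restricted to {CL, V1} take the fast scalar path;
    this covers the shipped concentrate models and keeps full-design
    evaluations tractable.
    """
    obs = _as_observation_list(observations)
    if model.omega_params and sorted(model.omega_params) != sorted(
        set(model.omega_params) & {"CL", "V1", "Q", "V2"}
    ):
        raise ValueError("omega_params must be PK parameters")

    typ = model.typical_values(covariates)
    tCL, tV1, tQ, tV2 = typ["CL"], typ["V1"], typ["Q"], typ["V2"]
    k = model.n_eta
    if k:
        omega_inv = np.linalg.inv(model.omega)
        _, logdet = np.linalg.slogdet(model.omega)
        prior_const = k * _LOG_2PI + logdet
    else:
        omega_inv = np.zeros((0, 0))
        prior_const = 0.0
    oi = omega_inv.tolist()
    idx = {p: i for i, p in enumerate(model.omega_params)}
    iCL, iV1 = idx.get("CL"), idx.get("V1")
    iQ, iV2 = idx.get("Q"), idx.get("V2")

    D = regimen.dose_iu
    tau = regimen.interval
    ss = regimen.steady_state
    sp2 = model.sigma_prop * model.sigma_prop
    sa2 = model.sigma_add * model.sigma_add
    lloq = model.lloq
    t_list = [o.realized_time for o in obs]
    y_list = [0.0 if o.bql else o.conc_observed for o in obs]
    bql_list = [o.bql for o in obs]

    def _exp_clamped(v: float) -> float:
        # keeps parameters strictly positive and finite for any line-search step
        return math.exp(-40.0 if v < -40.0 else (40.0 if v > 40.0 else v))

    def objective(eta: Sequence[float]) -> float:
        CL = tCL * _exp_clamped(eta[iCL]) if iCL is not None else tCL
        V1 = tV1 * _exp_clamped(eta[iV1]) if iV1 is not None else tV1
        Q = tQ * _exp_clamped(eta[iQ]) if iQ is not None else tQ
        V2 = tV2 * _exp_clamped(eta[iV2]) if iV2 is not None else tV2
        k10 = CL / V1
        k12 = Q / V1
        k21 = Q / V2
        s = k10 + k12 + k21
        disc = math.sqrt(max(s * s - 4.0 * k10 * k21, 1e-300))
        alpha = 0.5 * (s + disc)
        beta = max(0.5 * (s - disc), 1e-300)
        denom = V1 * (alpha - beta) * 1000.0
        A = (alpha - k21) / denom
        B = (k21 - beta) / denom
        if ss:
            A /= -math.expm1(-alpha * tau)
            B /= -math.expm1(-beta * tau)
        val = 0.0
        for t, y, bql in zip(t_list, y_list, bql_list):
            f = D * (A * math.exp(-alpha * t) + B * math.exp(-beta * t))
            g2 = f * f * sp2 + sa2
            if bql:
                val -= 2.0 * _log_phi((lloq - f) / math.sqrt(g2))
            else:
                r = y - f
                val += math.log(2.0 * math.pi * g2) + r * r / g2
        # prior penalty
        for i in range(k):
            row = oi[i]
            acc = 0.0
            for j in range(k):
                acc += row[j] * eta[j]
            val += eta[i] * acc
        return val + prior_const

    return objective


def neg2_log_posterior(
    eta: Sequence[float],
    model: PopulationPKModel,
    regimen: DoseRegimen,
    observations,
    covariates=None,
) -> float:
    """-2 log posterior at eta (prior-only when observations is empty)."""
    if covariates is None:
        covariates = {}
    return make_objective(model, covariates, regimen, observations)(np.asarray(eta, float))


def map_estimate(
    model: PopulationPKModel,
    covariates,
    regimen: DoseRegimen,
    observations,
    *,
    n_starts: int = 5,
    seed: int = 0,
    tol: float = 1e-8,
    trough_time: float | None = None,
    patient_id: int = -1,
    design_id: str = "",
) -> MAPResult:
    """MAP estimate of eta by multi-start quasi-Newton minimization.

    Starts at eta = 0 (the prior mode) plus ``n_starts - 1`` jittered points;
    the best objective wins. Patients whose samples are all BQL are still
    estimated (prior plus censoring information only).
    """
    obs = _as_observation_list(observations)
    k = model.n_eta
    objective = make_objective(model, covariates, regimen, obs)
    rng = np.random.default_rng(seed)
    jitter_sd = 0.5 * np.sqrt(np.diag(model.omega)) if k else np.zeros(0)

    starts = [np.zeros(k)]
    for _ in range(max(0, n_starts - 1)):
        starts.append(rng.standard_normal(k) * jitter_sd)

    best = None
    converged = False
    if k == 0:
        best_eta, best_val, converged = np.zeros(0), objective(np.zeros(0)), True
    else:
        for x0 in starts:
            x, fval, ok = minimize_bfgs_small(objective, list(x0), tol=tol)
            if not ok:
                # fall back to scipy's quasi-Newton for stubborn starts
                res = minimize(
                    objective, x, method="L-BFGS-B",
                    bounds=[(-8.0, 8.0)] * k,
                    options={"ftol": tol, "gtol": 1e-8, "maxiter": 200},
                )
                x, fval, ok = list(res.x), float(res.fun), bool(res.success)
            if best is None or fval < best[1]:
                best = (x, fval, ok)
        best_eta, best_val, converged = np.asarray(best[0]), float(best[1]), bool(best[2])

    params_hat = individual_parameters(model, covariates, best_eta)
    t_eval = regimen.interval if trough_time is None else trough_time
    trough = predict_trough(params_hat, regimen, t_eval)
    return MAPResult(
        patient_id=patient_id,
        design_id=design_id,
        eta_hat=best_eta,
        params_hat=params_hat,
        predicted_trough=trough,
        converged=converged,
        objective_value=best_val,
        n_bql_used=sum(o.bql for o in obs),
    )


def predict_trough(
    params: IndividualParameters, regimen: DoseRegimen, t_eval: float
) -> float:
    """Model-predicted steady-state level t_eval h post dose, no residual error."""
    return float(conc_steady_state(params, regimen, t_eval))
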