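"""Population pharmacokinetic model representation.

A two-compartment IV-bolus population model with log-normal inter-individual
variability (IIV) on a subset of the structural parameters and a combined
proportional + additive residual error. The model doubles as the Bayesian
prior for MAP estimation: typical values ``theta`` are scaled by covariate
relations (fat-free mass, age) and multiplied by ``exp(eta)`` for parameters
carrying IIV.

Units follow pharmacometric convention for FVIII: concentrations IU/ml,
doses IU, volumes L, clearances L/h, times h. The bi-exponential intercepts
A and B are therefore expressed in (IU/ml per IU dosed), i.e. A + B = 1/(1000·V1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "ConfigError",
    "CovariateRelation",
    "PopulationPKModel",
    "IndividualParameters",
    "individual_parameters",
    "macro_constants",
    "micro_from_macro",
    "load_model",
    "save_model",
]

PARAM_NAMES = ("CL", "V1", "Q", "V2")


class ConfigError(ValueError):
    """Raised when a model or demographics configuration violates its schema."""


@dataclass(frozen=True)
class CovariateRelation:
    """One multiplicative covariate effect on a structural parameter.

    form "power":  factor = (cov / reference_value) ** value
    form "linear": factor = 1 + value * (cov - reference_value)
    """

    parameter: str
    covariate: str
    form: str
    reference_value: float
    value: float

    def factor(self, covariates: Mapping[str, float]) -> float:
        if self.covariate not in covariates:
            raise ConfigError(
                f"covariate '{self.covariate}' required by relation on "
                f"'{self.parameter}' is missing"
            )
        cov = float(covariates[self.covariate])
        if self.form == "power":
            return (cov / self.reference_value) ** self.value
        if self.form == "linear":
            return 1.0 + self.value * (cov - self.reference_value)
        raise ConfigError(f"unknown covariate relation form '{self.form}'")


@dataclass
class PopulationPKModel:
    """Two-compartment population PK model with IIV and residual error."""

    name: str
    theta: dict[str, float]
    covariate_relations: list[CovariateRelation] = field(default_factory=list)
    omega: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    omega_params: list[str] = field(default_factory=list)
    sigma_prop: float = 0.0
    sigma_add: float = 0.0
    lloq: float = 0.01
    n_compartments: int = 2
    provenance: str = ""

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        errors = self.validation_errors()
        if errors:
            raise ConfigError("; ".join(errors))

    def validation_errors(self) -> list[str]:
        """Collect every violated invariant (empty list = valid)."""
        errs: list[str] = []
        if self.n_compartments != 2:
            errs.append(f"n_compartments must be 2, got {self.n_compartments}")
        for p in PARAM_NAMES:
            if p not in self.theta:
                errs.append(f"theta missing parameter '{p}'")
            elif not (self.theta[p] > 0):
                errs.append(f"theta[{p}] must be strictly positive")
        k = len(self.omega_params)
        if self.omega.shape != (k, k):
            errs.append(
                f"omega shape {self.omega.shape} does not match "
                f"{k} omega_params"
            )
        else:
            if k and not np.allclose(self.omega, self.omega.T):
                errs.append("omega must be symmetric")
            elif k:
                eig = np.linalg.eigvalsh(self.omega)
                if eig.min() < -1e-10:
                    errs.append("omega must be positive semi-definite")
            if any(p not in PARAM_NAMES for p in self.omega_params):
                errs.append("omega_params must be a subset of CL/V1/Q/V2")
        if self.sigma_prop < 0:
            errs.append("sigma_prop must be >= 0")
        if self.sigma_add < 0:
            errs.append("sigma_add must be >= 0")
        if self.sigma_prop == 0 and self.sigma_add == 0:
            errs.append("sigma_prop and sigma_add cannot both be 0")
        for rel in self.covariate_relations:
            if rel.form == "power" and not (rel.reference_value > 0):
                errs.append(
                    f"power relation on '{rel.parameter}' needs "
                    "reference_value > 0"
                )
        if not (self.lloq > 0):
            errs.append("lloq must be > 0")
        return errs

    @property
    def n_eta(self) -> int:
        return len(self.omega_params)

    def covariate_factors(self, covariates: Mapping[str, float]) -> dict[str, float]:
        """Multiplicative covariate factor per structural parameter."""
        fac = {p: 1.0 for p in PARAM_NAMES}
        for rel in self.covariate_relations:
            fac[rel.parameter] *= rel.factor(covariates)
        return fac

    def typical_values(self, covariates: Mapping[str, float]) -> dict[str, float]:
        fac = self.covariate_factors(covariates)
        return {p: self.theta[p] * fac[p] for p in PARAM_NAMES}

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n_compartments": self.n_compartments,
            "theta": {k: float(v) for k, v in self.theta.items()},
            "covariate_relations": [
                {
                    "parameter": r.parameter,
                    "covariate": r.covariate,
                    "form": r.form,
                    "reference_value": float(r.reference_value),
                    "value": float(r.value),
                }
                for r in self.covariate_relations
            ],
            "omega_params": list(self.omega_params),
            "omega": [[float(x) for x in row] for row in self.omega],
            "sigma_prop": float(self.sigma_prop),
            "sigma_add": float(self.sigma_add),
            "lloq": float(self.lloq),
            "provenance": self.provenance,
        }


def macro_constants(CL: float, V1: float, Q: float, V2: float):
    """Macro constants (alpha, beta, A, B) from micro parameters.

    alpha/beta are the fast/slow disposition rate constants (1/h); A and B
    the corresponding intercepts in IU/ml per IU dosed.
    """
    k10 = CL / V1
    k12 = Q / V1
    k21 = Q / V2
    s = k10 + k12 + k21
    disc = math.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    denom = V1 * (alpha - beta) * 1000.0  # L -> ml
    A = (alpha - k21) / denom
    B = (k21 - beta) / denom
    return alpha, beta, A, B


def micro_from_macro(alpha: float, beta: float, A: float, B: float):
    """Recover (CL, V1, Q, V2) from macro constants (inverse of macro_constants)."""
    V1 = 1.0 / (1000.0 * (A + B))
    k21 = (A * beta + B * alpha) / (A + B)
    k10 = alpha * beta / k21
    k12 = alpha + beta - k10 - k21
    CL = k10 * V1
    Q = k12 * V1
    V2 = Q / k21
    return CL, V1, Q, V2


@dataclass(frozen=True)
class IndividualParameters:
    """Individual micro parameters plus derived disposition quantities."""

    CL: float
    V1: float
    Q: float
    V2: float
    alpha: float
    beta: float
    A: float
    B: float

    @classmethod
    def from_micro(cls, CL: float, V1: float, Q: float, V2: float) -> "IndividualParameters":
        for name, v in (("CL", CL), ("V1", V1), ("Q", Q), ("V2", V2)):
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be finite and > 0, got {v}")
        alpha, beta, A, B = macro_constants(CL, V1, Q, V2)
        return cls(CL, V1, Q, V2, alpha, beta, A, B)

    @property
    def Vss(self) -> float:
        return self.V1 + self.V2

    @property
    def t_half(self) -> float:
        """Terminal (beta-phase) half-life in hours."""
        return math.log(2.0) / self.beta


def individual_parameters(
    model: PopulationPKModel,
    covariates: Mapping[str, float],
    eta: Sequence[float],
) -> IndividualParameters:
    """Map covariates and random effects to individual PK parameters.

    P_i = theta_P * covariate_factor_P(covariates) * exp(eta_P); parameters
    without IIV take eta = 0 implicitly.
    """
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (model.n_eta,):
        raise ValueError(
            f"eta has shape {eta.shape}, model expects ({model.n_eta},)"
        )
    typ = model.typical_values(covariates)
    vals = dict(typ)
    for i, p in enumerate(model.omega_params):
        vals[p] = typ[p] * math.exp(eta[i])
    for p, v in vals.items():
        if not math.isfinite(v):
            raise ValueError(f"non-finite individual parameter {p}={v}")
    return IndividualParameters.from_micro(vals["CL"], vals["V1"], vals["Q"], vals["V2"])


def _model_from_dict(data: dict) -> PopulationPKModel:
    try:
        relations = [
            CovariateRelation(
                parameter=r["parameter"],
                covariate=r["covariate"],
                form=r["form"],
                reference_value=float(r["reference_value"]),
                value=float(r["value"]),
            )
            for r in data.get("covariate_relations", [])
        ]
        return PopulationPKModel(
            name=data["name"],
            n_compartments=int(data.get("n_compartments", 2)),
            theta={k: float(v) for k, v in data["theta"].items()},
            covariate_relations=relations,
            omega=np.asarray(data.get("omega", []), dtype=float),
            omega_params=list(data.get("omega_params", [])),
            sigma_prop=float(data.get("sigma_prop", 0.0)),
            sigma_add=float(data.get("sigma_add", 0.0)),
            lloq=float(data.get("lloq", 0.01)),
            provenance=str(data.get("provenance", "")),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"malformed model config: {exc}") from exc


def load_model(path: str | Path) -> PopulationPKModel:
    """Load and validate a population PK model from a YAML/JSON config file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"model config not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"model config {path} is not a mapping")
    return _model_from_dict(data)


def save_model(model: PopulationPKModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model.to_dict(), fh, sort_keys=False)
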