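"""Design evaluation: bias/accuracy metrics, ranking and visit planning.

For each limited sampling strategy the simulate -> MAP-estimate loop yields,
per patient, estimated CL, V1, Vss, terminal half-life and the predicted
trough at the end of the dosing interval. Relative errors against the
simulation truth are summarized per stratum (adults >= 12 y, children < 12 y,
all) as mean percentage error (MPE, bias) and mean absolute percentage error
(MAPE, accuracy) with normal-approximation 95% CIs. A design is adequate
when MPE lies within +/-5% and MAPE <= 25%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import VirtualPatient
from .designs import SamplingDesign, builtin_designs, get_design
from .estimate import map_estimate
from .popmodel import PopulationPKModel
from .simulate import DoseRegimen, conc_steady_state, simulate_observations

__all__ = [
    "PARAMETERS",
    "relative_error",
    "mpe",
    "mape",
    "ci95_of_mean",
    "adequacy",
    "evaluate_design",
    "metrics_from_errors",
    "compare_designs",
    "VisitPlan",
    "plan_schedule",
]

PARAMETERS = ("CL", "V1", "Vss", "t_half", "trough")


def relative_error(theta_hat: float, theta_true: float) -> float:
    """Relative error in percent: (estimate - truth) / truth * 100."""
    if theta_true == 0:
        raise ZeroDivisionError("theta_true must be nonzero")
    return (theta_hat - theta_true) / theta_true * 100.0


def mpe(errors) -> float:
    """Mean percentage error (bias, %)."""
    errors = np.asarray(errors, dtype=float)
    if errors.size < 1:
        raise ValueError("need at least one error")
    return float(errors.mean())


def mape(errors) -> float:
    """Mean absolute percentage error (inaccuracy, %)."""
    errors = np.asarray(errors, dtype=float)
    if errors.size < 1:
        raise ValueError("need at least one error")
    return float(np.abs(errors).mean())


def ci95_of_mean(errors) -> tuple[float, float]:
    """Normal-approximation 95% CI of the mean: mean +/- 1.96 sd / sqrt(n)."""
    errors = np.asarray(errors, dtype=float)
    m = errors.mean()
    if errors.size < 2:
        return (float(m), float(m))
    half = 1.96 * errors.std(ddof=1) / np.sqrt(errors.size)
    return (float(m - half), float(m + half))


def adequacy(mpe_value: float, mape_value: float) -> bool:
    """Adequate when bias within -5..5% and inaccuracy not above 25%."""
    return (-5.0 <= mpe_value <= 5.0) and (mape_value <= 25.0)


def metrics_from_errors(
    errors: pd.DataFrame, design_id: str
) -> pd.DataFrame:
    """Summarize a per-patient relative-error table into metric rows.

    ``errors`` columns: stratum plus one column per evaluated parameter.
    """
    rows = []
    strata: list[tuple[str, pd.DataFrame]] = [("all", errors)]
    strata += [(name, errors[errors["stratum"] == name]) for name in ("adult", "child")]
    for stratum, sub in strata:
        if len(sub) == 0:
            continue
        for param in PARAMETERS:
            if param not in sub.columns:
                continue
            e = sub[param].to_numpy()
            m, a = mpe(e), mape(e)
            m_lo, m_hi = ci95_of_mean(e)
            a_lo, a_hi = ci95_of_mean(np.abs(e))
            rows.append(
                {
                    "design_id": design_id,
                    "stratum": stratum,
                    "parameter": param,
                    "mpe": m,
                    "mpe_lo": m_lo,
                    "mpe_hi": m_hi,
                    "mape": a,
                    "mape_lo": a_lo,
                    "mape_hi": a_hi,
                    "n": len(e),
                    "adequate": adequacy(m, a),
                }
            )
    return pd.DataFrame(rows)


def evaluate_design(
    design: SamplingDesign | str,
    patients: list[VirtualPatient],
    model: PopulationPKModel,
    interval: float,
    seed: int,
    *,
    trough_time: float | None = None,
    n_starts: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the simulate -> MAP loop for one design over a cohort.

    Returns (metrics table, per-patient table). All patients are retained,
    including those whose entire design is BQL and optimizer non-converged
    ones (kept at their best point).
    """
    if isinstance(design, str):
        design = get_design(design)
    t_eval = interval if trough_time is None else trough_time
    child_seeds = np.random.SeedSequence(seed).spawn(len(patients))

    records = []
    for patient, css in zip(patients, child_seeds):
        rng = np.random.default_rng(css)
        regimen = DoseRegimen(patient.dose_iu, interval)
        obs = simulate_observations(patient, design, model, regimen, rng)
        fit = map_estimate(
            model,
            patient.demographics.covariates,
            regimen,
            obs,
            n_starts=n_starts,
            seed=int(rng.integers(2**31 - 1)),
            trough_time=t_eval,
            patient_id=patient.demographics.patient_id,
            design_id=design.design_id,
        )
        true = patient.params_true
        true_trough = float(conc_steady_state(true, regimen, t_eval))
        rec = {
            "patient_id": patient.demographics.patient_id,
            "design_id": design.design_id,
            "stratum": "child" if patient.demographics.is_child else "adult",
            "converged": fit.converged,
            "n_bql": fit.n_bql_used,
            "true_CL": true.CL,
            "true_V1": true.V1,
            "true_Vss": true.Vss,
            "true_t_half": true.t_half,
            "true_trough": true_trough,
            "est_CL": fit.params_hat.CL,
            "est_V1": fit.params_hat.V1,
            "est_Vss": fit.params_hat.Vss,
            "est_t_half": fit.params_hat.t_half,
            "est_trough": fit.predicted_trough,
        }
        for param in PARAMETERS:
            rec[param] = relative_error(rec[f"est_{param}"], rec[f"true_{param}"])
        records.append(rec)

    per_patient = pd.DataFrame(records)
    metrics = metrics_from_errors(per_patient, design.design_id)
    return metrics, per_patient


def compare_designs(
    metrics: pd.DataFrame,
    stratum: str = "adult",
    trough_param: str = "trough",
    mape_exclusion: float = 25.0,
) -> pd.DataFrame:
    """Rank designs within each sample-count class by trough MAPE.

    Ties break on |MPE| and then on fewer samples (patient burden). Designs
    whose trough MAPE exceeds ``mape_exclusion`` are flagged excluded; the
    recommended design per class is the best non-excluded one.
    """
    if len(metrics) == 0:
        return pd.DataFrame(
            columns=["design_id", "n_samples", "mape", "mpe", "excluded", "rank", "recommended"]
        )
    lib = builtin_designs()
    sub = metrics[(metrics["stratum"] == stratum) & (metrics["parameter"] == trough_param)]
    rows = []
    for _, r in sub.iterrows():
        n_samp = lib[r["design_id"]].n_samples if r["design_id"] in lib else np.nan
        rows.append(
            {
                "design_id": r["design_id"],
                "n_samples": n_samp,
                "mape": r["mape"],
                "mpe": r["mpe"],
                "excluded": r["mape"] > mape_exclusion,
            }
        )
    out = pd.DataFrame(rows)
    out["_tie"] = list(zip(out["mape"], out["mpe"].abs(), out["n_samples"]))
    out = out.sort_values("_tie").drop(columns="_tie").reset_index(drop=True)
    out["rank"] = (
        out.groupby("n_samples")["mape"].rank(method="first").astype(int)
    )
    out["recommended"] = False
    for n_samp, grp in out.groupby("n_samples"):
        ok = grp[~grp["excluded"]]
        if len(ok):
            out.loc[ok.index[0], "recommended"] = True
    return out


@dataclass(frozen=True)
class VisitEvent:
    visit: int | None   # None = at home
    time_h: float       # relative to the EHL profile dose
    action: str         # "home-dose", "clinic-dose" or "sample"
    concentrate: str    # "EHL" or "SHL"
    label: str = ""


@dataclass(frozen=True)
class VisitPlan:
    events: tuple[VisitEvent, ...] = field(default_factory=tuple)

    @property
    def n_samples(self) -> int:
        return sum(e.action == "sample" for e in self.events)

    @property
    def n_visits(self) -> int:
        return len({e.visit for e in self.events if e.visit is not None})


def _profile_events(
    design: SamplingDesign,
    concentrate: str,
    interval: float,
    predose_reuse: bool,
    t0: float,
    visit0: int,
) -> tuple[list[VisitEvent], int]:
    """Visit events for one concentrate's profile dosed in clinic at t0."""
    times = sorted(design.nominal_times)
    peak = [t for t in times if t <= 0.5]
    others = [t for t in times if t > 0.5]
    events: list[VisitEvent] = []
    visit = visit0
    if predose_reuse and others:
        # trough sampled just before the clinic dose, timed one interval
        # after a home infusion; the latest design time doubles as predose
        trough_t = others.pop(-1)
        events.append(VisitEvent(None, t0 - interval, "home-dose", concentrate))
        events.append(
            VisitEvent(visit, t0, "sample", concentrate, f"{trough_t:g}h (predose)")
        )
    else:
        events.append(VisitEvent(visit, t0, "sample", concentrate, "predose"))
    events.append(VisitEvent(visit, t0, "clinic-dose", concentrate))
    for t in peak:
        events.append(VisitEvent(visit, t0 + t, "sample", concentrate, "peak"))
    for t in others:
        visit += 1
        events.append(VisitEvent(visit, t0 + t, "sample", concentrate, f"{t:g}h"))
    return events, visit


def plan_schedule(
    ehl_design: SamplingDesign | str,
    shl_design: SamplingDesign | str | None = None,
    mode: str = "combined",
    predose_reuse: bool = True,
    ehl_interval: float = 72.0,
    shl_interval: float = 48.0,
) -> VisitPlan:
    """Plan clinic visits for EHL-only, combined, or separate PK profiling.

    In combined mode the profiles interleave: the SHL trough (one SHL interval
    after a home SHL infusion) is drawn at the EHL dosing visit, and the SHL
    clinic dose is given at the EHL trough visit, so that trough samples and
    dosing visits are shared.
    """
    if isinstance(ehl_design, str):
        ehl_design = get_design(ehl_design)
    if isinstance(shl_design, str):
        shl_design = get_design(shl_design)

    if shl_design is None:
        events, _ = _profile_events(ehl_design, "EHL", ehl_interval, predose_reuse, 0.0, 1)
        return VisitPlan(tuple(events))

    if mode == "separate":
        ehl_events, last = _profile_events(
            ehl_design, "EHL", ehl_interval, predose_reuse, 0.0, 1
        )
        shl_t0 = max(e.time_h for e in ehl_events) + shl_interval
        shl_events, _ = _profile_events(
            shl_design, "SHL", shl_interval, predose_reuse, shl_t0, last + 1
        )
        return VisitPlan(tuple(ehl_events + shl_events))

    if mode != "combined":
        raise ValueError("mode must be 'combined' or 'separate'")

    # combined: SHL trough at the EHL dose visit, SHL dose at the EHL trough visit
    ehl_times = sorted(ehl_design.nominal_times)
    shl_times = sorted(shl_design.nominal_times)
    ehl_peak = [t for t in ehl_times if t <= 0.5]
    ehl_others = [t for t in ehl_times if t > 0.5]
    shl_peak = [t for t in shl_times if t <= 0.5]
    shl_others = [t for t in shl_times if t > 0.5]

    events: list[VisitEvent] = [VisitEvent(None, -shl_interval, "home-dose", "SHL")]
    visit = 1
    shl_trough_t = shl_others.pop(-1) if (predose_reuse and shl_others) else None
    if shl_trough_t is not None:
        events.append(VisitEvent(visit, 0.0, "sample", "SHL", f"{shl_trough_t:g}h (predose)"))
    else:
        events.append(VisitEvent(visit, 0.0, "sample", "SHL", "predose"))
    events.append(VisitEvent(visit, 0.0, "clinic-dose", "EHL"))
    for t in ehl_peak:
        events.append(VisitEvent(visit, t, "sample", "EHL", "peak"))

    ehl_trough_t = ehl_others.pop(-1) if ehl_others else ehl_interval
    for t in ehl_others:
        visit += 1
        events.append(VisitEvent(visit, t, "sample", "EHL", f"{t:g}h"))

    visit += 1
    events.append(VisitEvent(visit, ehl_trough_t, "sample", "EHL", f"{ehl_trough_t:g}h"))
    events.append(VisitEvent(visit, ehl_trough_t, "clinic-dose", "SHL"))
    for t in shl_peak:
        events.append(VisitEvent(visit, ehl_trough_t + t, "sample", "SHL", "peak"))
    for t in shl_others:
        visit += 1
        events.append(VisitEvent(visit, ehl_trough_t + t, "sample", "SHL", f"{t:g}h"))
    return VisitPlan(tuple(events))
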