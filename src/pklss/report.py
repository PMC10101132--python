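"""Experiment orchestration: config, artifact bundle, figures, toy fixture."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import cohort as _cohort
from .cohort import build_cohort, population_to_dataframe, sample_population
from .designs import get_design
from .estimate import map_estimate
from .evaluate import compare_designs, evaluate_design
from .popmodel import ConfigError, PopulationPKModel, individual_parameters, load_model
from .simulate import DoseRegimen, conc_steady_state, nonmem_dataset, simulate_observations

__all__ = ["RunConfig", "run_experiment", "make_toy_fixture", "default_model_path"]

_CONFIG_DIR = Path(__file__).parent / "configs"


def default_model_path(name: str) -> Path:
    """Path of a bundled model config ('bax855' or 'shl')."""
    p = _CONFIG_DIR / f"{name}.yaml"
    if not p.exists():
        raise ConfigError(f"no bundled model config '{name}'")
    return p


@dataclass
class RunConfig:
    """Configuration of one full simulation -> estimation -> metrics run."""

    model_path: str | Path
    design_ids: list[str]
    n: int = 10_000
    seed: int = 1
    iu_per_kg: float = 50.0
    interval: float = 72.0
    out_dir: str | Path = "results"
    demographics_path: str | Path | None = None
    n_starts: int = 5
    write_nonmem: bool = False
    figures: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        if not Path(self.model_path).exists():
            raise ConfigError(f"model config not found: {self.model_path}")
        if self.demographics_path is not None and not Path(self.demographics_path).exists():
            raise ConfigError(f"demographics config not found: {self.demographics_path}")


def _config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(
        {
            "model": str(cfg.model_path),
            "designs": cfg.design_ids,
            "n": cfg.n,
            "seed": cfg.seed,
            "iu_per_kg": cfg.iu_per_kg,
            "interval": cfg.interval,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_experiment(cfg: RunConfig) -> dict:
    """Run the full pipeline and write the artifact bundle; returns a manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = load_model(cfg.model_path)
    ss = np.random.SeedSequence(cfg.seed)
    seeds = {name: int(s.generate_state(1)[0] % (2**31 - 1))
             for name, s in zip(("population", "etas", "evaluate"), ss.spawn(3))}

    demog = sample_population(cfg.n, seeds["population"], cfg.demographics_path)
    patients = build_cohort(model, demog, cfg.iu_per_kg, seeds["etas"])
    pop_df = population_to_dataframe(patients)
    pop_df.to_csv(out / "population.csv", index=False, float_format="%.6g")

    all_metrics, all_patients = [], []
    for design_id in cfg.design_ids:
        metrics, per_patient = evaluate_design(
            get_design(design_id), patients, model, cfg.interval,
            seeds["evaluate"], n_starts=cfg.n_starts,
        )
        all_metrics.append(metrics)
        all_patients.append(per_patient)
    metrics_df = pd.concat(all_metrics, ignore_index=True)
    per_patient_df = pd.concat(all_patients, ignore_index=True)
    metrics_df.to_csv(out / "metrics.csv", index=False, float_format="%.6g")
    per_patient_df.to_csv(out / "map_results.csv", index=False, float_format="%.6g")
    ranking = compare_designs(metrics_df)
    ranking.to_csv(out / "ranking.csv", index=False, float_format="%.6g")

    if cfg.write_nonmem:
        rng = np.random.default_rng(seeds["evaluate"])
        obs_sets = [
            simulate_observations(
                p, get_design(cfg.design_ids[0]), model,
                DoseRegimen(p.dose_iu, cfg.interval), rng,
            )
            for p in patients[: min(cfg.n, 100)]
        ]
        nonmem_dataset(patients, obs_sets).to_csv(out / "nonmem_dataset.csv", index=False)

    if cfg.figures:
        plot_profiles(patients, model, cfg.interval, out / "fig_profiles.png",
                      seed=seeds["evaluate"])
        plot_error_boxplots(per_patient_df, out / "fig_relative_errors.png")

    manifest = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "stage_seeds": seeds,
        "model": model.name,
        "designs": cfg.design_ids,
        "n": cfg.n,
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def plot_profiles(patients, model, interval, path, seed=0, n_show=300, t_max=96.0):
    """Spaghetti plot of steady-state FVIII profiles, faceted by stratum."""
    t = np.linspace(0.0, t_max, 200)
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, stratum in zip(axes, ("adult", "child")):
        subset = [p for p in patients
                  if ("child" if p.demographics.is_child else "adult") == stratum]
        for p in subset[:n_show]:
            c = conc_steady_state(p.params_true, DoseRegimen(p.dose_iu, interval), t)
            ax.plot(t, c, lw=0.3, alpha=0.3, color="tab:blue")
        ax.axhline(model.lloq, ls=":", color="k", label=f"LLOQ {model.lloq} IU/ml")
        ax.set_yscale("log")
        ax.set_xlabel("time after dose (h)")
        ax.set_title(f"{stratum}s (n={len(subset)})")
        ax.legend(loc="upper right", fontsize=8)
    axes[0].set_ylabel("FVIII (IU/ml)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_error_boxplots(per_patient: pd.DataFrame, path,
                        params=("t_half", "trough"), clip=50.0):
    """Relative-error boxplots per design; whiskers at the 5th/95th percentile."""
    designs = sorted(per_patient["design_id"].unique())
    fig, axes = plt.subplots(len(params), 1, figsize=(1.2 * len(designs) + 2, 3.2 * len(params)),
                             squeeze=False)
    for ax, param in zip(axes[:, 0], params):
        data = [per_patient.loc[per_patient["design_id"] == d, param].to_numpy()
                for d in designs]
        ax.boxplot(data, tick_labels=designs, whis=(5, 95), showfliers=False)
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_ylabel(f"{param} rel. error (%)")
        if param == "trough":
            ax.set_ylim(-clip, clip)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def make_toy_fixture(seed: int = 0):
    """Tiny deterministic two-compartment model plus 5 virtual patients.

    The printed parameters are round numbers so that unit tests and
    grid-search oracles can be hand-checked.
    """
    model = PopulationPKModel(
        name="toy",
        theta={"CL": 0.2, "V1": 3.0, "Q": 0.15, "V2": 2.0},
        covariate_relations=[],
        omega=np.array([[0.09, 0.0], [0.0, 0.04]]),
        omega_params=["CL", "V1"],
        sigma_prop=0.10,
        sigma_add=0.001,
        lloq=0.01,
        provenance="synthetic toy fixture for tests",
    )
    rng = np.random.default_rng(seed)
    etas = rng.multivariate_normal(np.zeros(2), model.omega, size=5)
    patients = []
    for i in range(5):
        demog = _cohort.Demographics(
            patient_id=i, age=30.0, body_weight=70.0, bmi=23.0,
            ffm=_cohort.compute_ffm(30.0, 70.0, 23.0),
        )
        params = individual_parameters(model, demog.covariates, etas[i])
        patients.append(
            _cohort.VirtualPatient(
                demographics=demog, eta_true=etas[i],
                params_true=params, dose_iu=3500.0,
            )
        )
    return model, patients
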