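"""Kinetics and observation simulation: closed forms, windows, error, censoring."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.stats import kstest

from pklss.designs import SampleSpec, SamplingDesign, get_design
from pklss.popmodel import IndividualParameters
from pklss.simulate import (
    DoseRegimen,
    Observation,
    ObservationSet,
    add_residual_error,
    bql_fraction,
    censor,
    conc_single_dose,
    conc_steady_state,
    nonmem_dataset,
    realize_times,
    simulate_observations,
)

PARAMS = IndividualParameters.from_micro(CL=0.2, V1=3.0, Q=0.15, V2=2.0)


def _ode_conc(params, dose, times):
    """Independent oracle: adaptive integration of the two-compartment system."""
    k10 = params.CL / params.V1
    k12 = params.Q / params.V1
    k21 = params.Q / params.V2

    def rhs(_t, y):
        return [-(k10 + k12) * y[0] + k21 * y[1], k12 * y[0] - k21 * y[1]]

    sol = solve_ivp(rhs, (0.0, max(times)), [dose, 0.0], t_eval=times,
                    rtol=1e-11, atol=1e-12, method="LSODA")
    return sol.y[0] / (1000.0 * params.V1)


def test_bolus_initial_condition():
    assert conc_single_dose(PARAMS, 2000.0, 0.0) == pytest.approx(
        2000.0 / (1000.0 * 3.0), rel=1e-12
    )


def test_zero_dose_zero_everywhere():
    assert conc_single_dose(PARAMS, 0.0, np.array([0.0, 4.0, 48.0])).max() == 0.0


def test_single_dose_matches_ode_oracle():
    times = np.array([4.0, 24.0, 48.0])
    closed = conc_single_dose(PARAMS, 2000.0, times)
    numeric = _ode_conc(PARAMS, 2000.0, times)
    assert np.allclose(closed, numeric, rtol=1e-8)


def test_steady_state_reduces_to_single_dose_for_huge_interval():
    reg = DoseRegimen(2000.0, interval=1e7)
    t = np.array([0.5, 24.0, 72.0])
    assert np.allclose(conc_steady_state(PARAMS, reg, t),
                       conc_single_dose(PARAMS, 2000.0, t), rtol=1e-9)


def test_steady_state_matches_brute_force_superposition():
    reg = DoseRegimen(3500.0, interval=72.0)
    t = np.array([0.375, 4.0, 24.0, 48.0, 72.0, 96.0])
    brute = sum(conc_single_dose(PARAMS, 3500.0, t + k * 72.0) for k in range(60))
    assert np.allclose(conc_steady_state(PARAMS, reg, t), brute, rtol=1e-6)


def test_steady_state_periodicity_when_next_dose_given():
    """C_ss(t) = single(t) + C_ss(t + tau with the next dose withheld)."""
    reg = DoseRegimen(3500.0, interval=72.0)
    for t in (0.3, 10.0, 50.0):
        lhs = conc_steady_state(PARAMS, reg, t)
        rhs = conc_single_dose(PARAMS, 3500.0, t) + conc_steady_state(PARAMS, reg, t + 72.0)
        assert lhs == pytest.approx(rhs, rel=1e-12)


def test_accumulation_never_below_one():
    reg = DoseRegimen(1000.0, interval=72.0)
    t = np.linspace(0, 72, 50)
    assert (conc_steady_state(PARAMS, reg, t) >= conc_single_dose(PARAMS, 1000.0, t)).all()


def test_terminal_phase_monotone_decay():
    t = np.linspace(5.0 / PARAMS.alpha, 200.0, 300)
    c = conc_single_dose(PARAMS, 2000.0, t)
    assert (np.diff(c) < 0).all()
    assert (c > 0).all()


def test_realized_times_stay_in_windows(rng):
    design = get_design("LSS1")
    for _ in range(200):
        times = realize_times(design, rng)
        assert len(times) == design.n_samples
        assert (np.diff(times) >= 0).all()
        # the 48 h sample always falls in 44-52 h
        assert ((times > 44.0) & (times < 52.0)).any()
        for spec in design.sample_specs:
            lo, hi = spec.window
            assert ((times >= lo) & (times <= hi)).sum() >= spec.multiplicity


def test_zero_width_window_returns_nominal(rng):
    design = SamplingDesign("fixed", (SampleSpec(0.375, 0.0), SampleSpec(48.0, 0.0)))
    assert realize_times(design, rng).tolist() == [0.375, 48.0]


def test_window_draws_are_uniform(rng):
    draws = np.array([realize_times(get_design("LSS14"), rng)[-1] for _ in range(10_000)])
    assert kstest(draws, "uniform", args=(44.0, 8.0)).pvalue > 0.01


def test_duplicate_sample_design_draws_two_in_one_window(rng):
    times = realize_times(get_design("LSS11"), rng)
    assert len(times) == 3
    assert ((times >= 44.0) & (times <= 52.0)).sum() == 2


def test_residual_error_degenerates_to_truth(bax_model, rng):
    import copy

    noiseless = copy.deepcopy(bax_model)
    noiseless.sigma_prop = 0.0
    noiseless.sigma_add = 1e-300  # avoid the both-zero invariant
    assert add_residual_error(0.5, noiseless, rng) == pytest.approx(0.5, abs=1e-12)


def test_residual_error_moments(bax_model, rng):
    f = 0.5
    y = add_residual_error(np.full(100_000, f), bax_model, rng)
    se = f * bax_model.sigma_prop / np.sqrt(len(y))
    assert abs(y.mean() - f) < 3 * se
    expected_var = f**2 * bax_model.sigma_prop**2 + bax_model.sigma_add**2
    assert abs(y.var() / expected_var - 1.0) < 0.05


@pytest.mark.parametrize("value,expected_bql", [(0.009, True), (0.010, False), (0.0, True)])
def test_censoring_is_strictly_below_lloq(value, expected_bql):
    obs = censor(value, lloq=0.01)
    assert obs.bql is expected_bql
    assert (obs.conc_observed is None) == expected_bql


def test_censoring_preserves_count(small_cohort, bax_model, rng):
    design = get_design("LSS1")
    reg = DoseRegimen(small_cohort[0].dose_iu, 72.0)
    oset = simulate_observations(small_cohort[0], design, bax_model, reg, rng)
    assert len(oset.observations) == design.n_samples


def test_observation_times_must_increase():
    o = Observation(1.0, 1.0, 0.5, False, 0.01)
    with pytest.raises(ValueError, match="strictly increasing"):
        ObservationSet(0, DoseRegimen(100.0, 72.0), (o, o))


def test_bql_fraction_zero_for_negligible_lloq(small_cohort, bax_model):
    import copy

    m = copy.deepcopy(bax_model)
    m.lloq = 1e-12
    m.sigma_add = 0.0
    fr = bql_fraction(small_cohort, m, 50.0, 72.0, (70.0, 74.0), seed=5)
    assert fr["all"] == 0.0


def test_nonmem_dataset_structure(small_cohort, bax_model, rng):
    design = get_design("LSS7")
    osets = [
        simulate_observations(p, design, bax_model, DoseRegimen(p.dose_iu, 72.0), rng)
        for p in small_cohort[:5]
    ]
    df = nonmem_dataset(small_cohort[:5], osets)
    doses = df[df.EVID == 1]
    obs = df[df.EVID == 0]
    assert len(doses) == 5 and (doses.SS == 1).all()
    assert len(obs) == 5 * design.n_samples
    assert (obs.loc[obs.BLQ == 1, "DV"] == bax_model.lloq).all()
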