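"""MAP estimator: M3 likelihood, optimization, trough prediction."""

import copy
import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from pklss.designs import get_design
from pklss.estimate import make_objective, map_estimate, neg2_log_posterior, predict_trough
from pklss.popmodel import IndividualParameters, individual_parameters
from pklss.simulate import (
    DoseRegimen,
    Observation,
    censor,
    conc_steady_state,
    simulate_observations,
)

COV = {"ffm": 56.0, "age": 30.0, "weight": 70.0, "bmi": 23.0}


def _quantified(t, y, lloq=0.01):
    return Observation(t, t, y, False, lloq)


def _bql(t, lloq=0.01):
    return Observation(t, t, None, True, lloq)


def test_prior_only_minimized_at_zero(toy):
    model, _ = toy
    reg = DoseRegimen(3500.0, 72.0)
    res = map_estimate(model, COV, reg, [], seed=1)
    assert np.allclose(res.eta_hat, 0.0, atol=1e-6)
    # objective at the prior mode is exactly the prior normalization
    expected = 2 * math.log(2 * math.pi) + math.log(np.linalg.det(model.omega))
    assert neg2_log_posterior([0.0, 0.0], model, reg, [], COV) == pytest.approx(expected)


def test_no_bql_reduces_to_gaussian_likelihood(toy):
    """Without censored samples the M3 objective is the plain Gaussian -2LL + prior."""
    model, patients = toy
    reg = DoseRegimen(3500.0, 72.0)
    obs = [_quantified(0.4, 1.10), _quantified(48.0, 0.11), _quantified(71.0, 0.035)]
    eta = np.array([0.2, -0.1])
    got = neg2_log_posterior(eta, model, reg, obs, COV)

    params = individual_parameters(model, COV, eta)
    expected = 0.0
    for o in obs:
        f = conc_steady_state(params, reg, o.realized_time)
        g2 = f**2 * model.sigma_prop**2 + model.sigma_add**2
        expected += math.log(2 * math.pi * g2) + (o.conc_observed - f) ** 2 / g2
    oinv = np.linalg.inv(model.omega)
    expected += float(eta @ oinv @ eta)
    expected += 2 * math.log(2 * math.pi) + math.log(np.linalg.det(model.omega))
    assert got == pytest.approx(expected, rel=1e-12)


def test_bql_term_matches_gaussian_tail_quadrature(toy):
    """The M3 contribution equals -2 log of the censored probability mass."""
    model, _ = toy
    reg = DoseRegimen(3500.0, 72.0)
    eta = np.array([0.1, 0.05])
    params = individual_parameters(model, COV, eta)
    t = 90.0
    f = conc_steady_state(params, reg, t)
    g = math.sqrt(f**2 * model.sigma_prop**2 + model.sigma_add**2)

    base = neg2_log_posterior(eta, model, reg, [], COV)
    with_bql = neg2_log_posterior(eta, model, reg, [_bql(t)], COV)
    mass, _ = quad(lambda y: norm.pdf(y, loc=f, scale=g), -50 * g + f, 0.01)
    assert with_bql - base == pytest.approx(-2.0 * math.log(mass), rel=1e-7)


def test_bql_term_limits(toy):
    model, _ = toy
    reg = DoseRegimen(3500.0, 72.0)
    lo = copy.deepcopy(model)
    # prediction far below LLOQ -> censoring is certain, no penalty
    eta_low = np.array([2.0, 0.0])  # huge CL -> tiny trough
    contrib_low = neg2_log_posterior(eta_low, model, reg, [_bql(96.0)], COV) - \
        neg2_log_posterior(eta_low, model, reg, [], COV)
    assert contrib_low == pytest.approx(0.0, abs=1e-4)
    # prediction far above LLOQ -> censoring nearly impossible, large penalty
    eta_high = np.array([-1.5, 0.0])
    contrib_high = neg2_log_posterior(eta_high, lo, reg, [_bql(4.0)], COV) - \
        neg2_log_posterior(eta_high, lo, reg, [], COV)
    assert contrib_high > 100.0


def test_m3_equivalence_deleting_bql_changes_only_phi_term(toy):
    model, _ = toy
    reg = DoseRegimen(3500.0, 72.0)
    quant = [_quantified(0.4, 1.1), _quantified(48.0, 0.1)]
    eta = np.array([-0.3, 0.2])
    diff = neg2_log_posterior(eta, model, reg, quant + [_bql(96.0)], COV) - \
        neg2_log_posterior(eta, model, reg, quant, COV)
    params = individual_parameters(model, COV, eta)
    f = conc_steady_state(params, reg, 96.0)
    g = math.sqrt(f**2 * model.sigma_prop**2 + model.sigma_add**2)
    assert diff == pytest.approx(-2.0 * norm.logcdf((0.01 - f) / g), rel=1e-9)


def test_map_matches_grid_search_oracle(toy):
    """2-D argmin agrees with exhaustive grid search within one grid step."""
    model, patients = toy
    patient = patients[2]
    reg = DoseRegimen(patient.dose_iu, 72.0)
    obs = simulate_observations(patient, get_design("LSS7"), model, reg,
                                np.random.default_rng(8))
    objective = make_objective(model, patient.demographics.covariates, reg, obs)
    step = 0.01
    grid = np.arange(-2.0, 2.0 + step / 2, step)
    vals = np.array([[objective((e1, e2)) for e2 in grid] for e1 in grid])
    i, j = np.unravel_index(np.argmin(vals), vals.shape)

    res = map_estimate(model, patient.demographics.covariates, reg, obs, seed=3)
    assert abs(res.eta_hat[0] - grid[i]) <= step
    assert abs(res.eta_hat[1] - grid[j]) <= step
    assert res.objective_value <= vals[i, j] + 1e-9


def test_noise_free_recovery_on_rich_design(bax_model, small_cohort):
    """With sigma -> 0 and six quantified samples, CL is recovered to 0.1%."""
    model = copy.deepcopy(bax_model)
    model.sigma_prop = 1e-4
    model.sigma_add = 1e-12
    for patient in small_cohort[:10]:
        reg = DoseRegimen(patient.dose_iu, 72.0)
        obs = simulate_observations(patient, get_design("LSS1"), model, reg,
                                    np.random.default_rng(99))
        if any(o.bql for o in obs.observations):
            continue
        res = map_estimate(model, patient.demographics.covariates, reg, obs, seed=0)
        assert res.params_hat.CL == pytest.approx(patient.params_true.CL, rel=1e-3)


def test_all_bql_objective_not_worse_than_prior_mode(toy):
    model, patients = toy
    patient = patients[0]
    reg = DoseRegimen(patient.dose_iu, 72.0)
    obs = [_bql(48.0), _bql(72.0)]
    res = map_estimate(model, patient.demographics.covariates, reg, obs, seed=0)
    at_zero = neg2_log_posterior(np.zeros(2), model, reg, obs,
                                 patient.demographics.covariates)
    assert res.objective_value <= at_zero + 1e-9
    assert res.n_bql_used == 2


def test_prior_dominance_as_omega_shrinks(toy):
    model, patients = toy
    tight = copy.deepcopy(model)
    tight.omega = np.array([[1e-6, 0.0], [0.0, 1e-6]])
    patient = patients[1]
    reg = DoseRegimen(patient.dose_iu, 72.0)
    obs = simulate_observations(patient, get_design("LSS7"), model, reg,
                                np.random.default_rng(4))
    res = map_estimate(tight, patient.demographics.covariates, reg, obs, seed=0)
    assert np.abs(res.eta_hat).max() < 5e-3


def test_estimator_consistency_small_sigma(bax_model):
    """Mean |relative CL error| over 200 patients stays below 2% for a rich,
    nearly noise-free design."""
    from pklss.cohort import build_cohort, sample_population

    model = copy.deepcopy(bax_model)
    model.sigma_prop = 0.02
    model.sigma_add = 1e-6
    patients = build_cohort(model, sample_population(200, 11), 50.0, 12)
    errs = []
    for i, p in enumerate(patients):
        reg = DoseRegimen(p.dose_iu, 72.0)
        obs = simulate_observations(p, get_design("LSS1"), model, reg,
                                    np.random.default_rng(i))
        res = map_estimate(model, p.demographics.covariates, reg, obs,
                           seed=i, n_starts=2)
        errs.append(abs(res.params_hat.CL / p.params_true.CL - 1.0))
    assert np.mean(errs) < 0.02


def test_predicted_trough_exact_for_true_parameters(toy):
    _, patients = toy
    p = patients[0]
    reg = DoseRegimen(p.dose_iu, 72.0)
    assert predict_trough(p.params_true, reg, 72.0) == pytest.approx(
        float(conc_steady_state(p.params_true, reg, 72.0))
    )
    assert predict_trough(p.params_true, reg, 1e-9) >= predict_trough(p.params_true, reg, 72.0)


def test_trough_one_compartment_limit():
    """With negligible inter-compartmental clearance the steady-state trough
    collapses to the one-compartment closed form."""
    CL, V1, tau, D = 0.2, 3.0, 72.0, 3500.0
    params = IndividualParameters.from_micro(CL, V1, 1e-9, 1.0)
    k = CL / V1
    expected = D / (1000.0 * V1) * math.exp(-k * tau) / (1.0 - math.exp(-k * tau))
    got = predict_trough(params, DoseRegimen(D, tau), tau)
    assert got == pytest.approx(expected, rel=1e-4)
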