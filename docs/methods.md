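# Methods

## Scope and model

`pklss` evaluates limited sampling strategies (LSS) for Bayesian
individualization of FVIII prophylaxis entirely in silico. The pipeline is
a parameter-recovery experiment: simulate a virtual patient's *true* PK,
generate the sparse noisy observations a clinic would actually collect
under a candidate design, re-estimate the patient's PK from those samples
with the population model as prior, and measure how far the estimates fall
from the truth.

### Structural and statistical model

Disposition is a two-compartment IV-bolus model parameterized by clearance
CL (L/h), central volume V1 (L), inter-compartmental clearance Q (L/h) and
peripheral volume V2 (L). Closed-form kinetics use the macro constants

    alpha·beta = (CL/V1)(Q/V2),  alpha+beta = CL/V1 + Q/V1 + Q/V2,
    C(t) = D (A e^{-alpha t} + B e^{-beta t}),   A + B = 1/V1,

with concentrations in IU/ml (1 IU/ml = 100% of normal activity), doses in
IU, times in hours. Under every-τ dosing at steady state each exponential
term is multiplied by 1/(1−e^{−λτ}). Evaluating that expression at t > τ
describes the profiled interval with the next dose withheld, which is how a
96-h sample exists under q72h dosing. Patients with severe hemophilia A are
assumed to have no endogenous baseline FVIII. Derived quantities: Vss =
V1+V2 and the terminal half-life t½ = ln2/β.

Individual parameters arise as `P_i = θ_P · f_P(cov) · exp(η_P)` with
covariate factors `f` (power-of-ratio or linear-in-centered forms) and
`η ~ N(0, Ω)` on CL and V1. Residual error is combined proportional +
additive, `y = f(1+ε_p) + ε_a`; negative draws are floored at zero (they
are censored anyway). Observations strictly below the LLOQ (0.01 IU/ml) are
below-quantification-limit (BQL) and masked.

### MAP estimation with censored data (M3)

For each patient/design the random effects are estimated by minimizing

    −2 log posterior(η) = Σ_quant [ log(2π g²) + (y−f)²/g² ]
                        + Σ_BQL  [ −2 log Φ((LLOQ−f)/g) ]
                        + η' Ω⁻¹ η + log|2π Ω|,

with `f` the steady-state prediction at the *realized* sampling time and
`g² = f²σ_p² + σ_a²` evaluated at the prediction (standard M3 treatment of
censored samples). Patients whose entire design is BQL are retained — the
prior plus the censoring information still define a posterior mode.

The optimizer is a dense BFGS with central-difference gradients and Armijo
backtracking (`pklss._bfgs`), written for the 2-dimensional η problems that
are evaluated hundreds of thousands of times per study; any start that
fails its convergence checks is retried with scipy's L-BFGS-B. Each fit is
multi-start: η = 0 plus four jittered starts (N(0, 0.5·√diagΩ)), best
objective kept, convergence tolerance 1e-8 on the objective. The posterior
is smooth and in practice unimodal; the multi-start plus the grid-search
oracle in the tests guard the claim.

The trough (C72 for the EHL regimen, C48 for SHL) is the model-predicted
steady-state level at the end of the dosing interval without residual
error, for both truth and estimate; the final design sample doubles as the
predose level, so no separate predose record exists.

### Metrics and design selection

Relative error `(θ̂−θ_true)/θ_true × 100%` per patient; per design,
stratum (adults ≥12 y, children <12 y, all) and parameter (CL, V1, Vss,
t½, trough) the bias MPE (mean error) and accuracy MAPE (mean absolute
error) with normal-approximation 95% CIs (mean ± 1.96·sd/√n — the CI
method behind published tables of this kind is rarely stated; symmetric
normal CIs are the simplest consistent choice). Adequacy: −5% ≤ MPE ≤ 5%
and MAPE ≤ 25% (bounds inclusive). Ranking is within sample-count class by
trough MAPE, ties by |MPE| then fewer samples; designs with trough MAPE
above 25% are excluded from recommendation.

## Synthetic data generator

The generator defines the study conditions and is not a tuning dial.

* **Demographics** (`configs/demographics.yaml`): stratum ~ Bernoulli
  (11.67% children), child age 3+9·Beta(2.4,1.2) (median ≈ 9.3 y), adult
  age truncated log-normal (median 24, σ_log 0.8, range 12–72). Weight is
  log-normal around an age-dependent median growth curve (log-linear
  between knots), BMI likewise; both truncated to the observed ranges by
  rejection. FFM follows the Al-Sallami male maturation formula (all
  patients male — severe hemophilia A is X-linked). A 10,000-draw cohort
  reproduces the reference summaries: ~11.7% children, median weight
  ~70.7 kg, median FFM ~55 kg.
* **PK models** (`configs/bax855.yaml`, `configs/shl.yaml`): the published
  sources state the structures (EHL: CL depends on FFM and age, V1 on FFM;
  SHL: body-size-scaled disposition) but the numeric values shipped here
  are **reconstructions**, fixed once against the concentrates' published
  typical PK: EHL adult t½ ≈ 14.9 h, CL ≈ 2.3 ml/h/kg, Vss ≈ 49 ml/kg; SHL
  t½ ≈ 11.7 h. All four structural parameters scale linearly with FFM, so
  weight-based dosing yields nearly size-independent profiles, consistent
  with the small adult/child difference in censoring rates; a linear age
  effect on CL (−0.005/y around 22.5 y) gives children ~7% higher
  clearance. IIV: sd(lnCL)=0.30, sd(lnV1)=0.20–0.21, correlation 0.45.
  Residual error: 20% proportional (one-stage assay scale) + 0.002 IU/ml
  additive.
* **Dosing**: 50 IU/kg q72h (EHL) and 40 IU/kg q48h (SHL), rounded to the
  nearest 250 IU vial (round-half-up).
* **Sampling windows**: uniform draws (maximum-entropy choice over a stated
  interval): peak U(0.25, 0.5) h, 4 h ± 1 h, later samples ± 4 h;
  duplicate-sample designs draw two independent times in one window and
  sort them.

What the generator does **not** emulate: assay discrepancies (one-stage vs
chromogenic), adherence variability and missed doses, carry-over of the
previous concentrate's residual level when switching, endogenous FVIII,
within-patient (inter-occasion) PK variability, and covariate measurement
error. Passing tests therefore demonstrate internal consistency of the
estimation machinery under the assumed population model, not performance
against real patient data; accuracy under model misspecification is
untested by construction.

## Numerical choices

* Macro-constant computation guards the discriminant at 0 and the slow rate
  at a positive floor; η is clamped to ±40 inside the objective so that any
  line-search step keeps parameters positive and finite.
* log Φ uses `erfc` directly down to x = −10 and the two-term asymptotic
  expansion beyond, avoiding underflow for predictions far above the LLOQ.
* Noise-free identifiability tests use σ_p = 1e-4 rather than exactly 0:
  the likelihood curvature scales as 1/σ², and finite-difference gradients
  degrade on the resulting stiff objective while the statistical error at
  1e-4 (~0.01%) is far below the 0.1% tolerance being checked.
* Ties at age exactly 12.0 y fall in the adult stratum (children are
  strictly <12 y).
* Reproducibility: every entry point takes one master seed; stage seeds are
  spawned via `numpy.random.SeedSequence` and recorded in the run manifest.

## Problem sizes

The analysis drivers default to n = 2,000 patients (design metrics are
stable to a fraction of a percentage point at that size); the acceptance
script and the full-scale test use the study size of n = 10,000. The
parameter-recovery ladder test uses n = 1,000, where the six- vs three- vs
two-sample ordering already exceeds twice its Monte Carlo standard error.

## Known limitations

* The shipped model parameterizations are reconstructions (see above), so
  absolute error levels shift with the assumed ω/σ; the qualitative design
  ranking — richer designs dominate, late-only sparse designs fail on the
  trough because ~10% (adults) to ~15% (children) of 72-h and ~40–52% of
  96-h samples are censored — is robust to that choice.
* The MAP point estimate ignores posterior uncertainty; no shrinkage
  diagnostics are reported.
* The visit planner covers the supported nominal grid (peak, 4, 24, 48, 72,
  96 h) and the three standard logistics; it does not optimize schedules.
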