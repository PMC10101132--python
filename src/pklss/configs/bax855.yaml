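# Population PK model for BAX 855 (Adynovi/Adynovate), PEGylated extended
# half-life recombinant FVIII, one-stage assay scale.
#
# Provenance: reconstructed parameterization. Structure follows the published
# WAPPS-Hemo BAX 855 model (two compartments; CL depends on fat-free mass and
# age, V1 on fat-free mass); numeric values were calibrated once to the
# concentrate's published typical adult PK (terminal t1/2 ~ 14.9 h,
# CL ~ 2.3 ml/h/kg, Vss ~ 49 ml/kg for a 70-kg adult with FFM 56 kg) with
# log-normal IIV on CL and V1 and combined proportional + additive residual
# error on the one-stage assay.
name: bax855
n_compartments: 2
theta:        # typical values at FFM = 56 kg, age = 22.5 y
  CL: 0.165   # L/h
  V1: 2.80    # L
  Q: 0.150    # L/h
  V2: 0.60    # L
covariate_relations:
  - {parameter: CL, covariate: ffm, form: power, reference_value: 56.0, value: 1.0}
  - {parameter: CL, covariate: age, form: linear, reference_value: 22.5, value: -0.005}
  - {parameter: V1, covariate: ffm, form: power, reference_value: 56.0, value: 1.0}
  - {parameter: Q,  covariate: ffm, form: power, reference_value: 56.0, value: 1.0}
  - {parameter: V2, covariate: ffm, form: power, reference_value: 56.0, value: 1.0}
omega_params: [CL, V1]
omega:        # log-normal IIV: sd(lnCL)=0.30, sd(lnV1)=0.20, corr 0.45
  - [0.0900, 0.0270]
  - [0.0270, 0.0400]
sigma_prop: 0.20    # proportional residual SD (fraction, one-stage assay)
sigma_add: 0.002    # additive residual SD (IU/ml)
lloq: 0.01          # IU/ml
provenance: reconstructed (see header comment)
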