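# Population PK model for a standard half-life (SHL) recombinant FVIII
# concentrate.
#
# Provenance: reconstructed parameterization. Structure follows the Björkman
# population model for recombinant FVIII (two compartments, body-size scaled
# disposition, mild age effect on clearance); numeric values were calibrated
# once to published typical adult SHL PK (terminal t1/2 ~ 11.7 h,
# CL ~ 3.0 ml/h/kg, Vss ~ 49 ml/kg for a 70-kg adult with FFM 56 kg).
name: shl
n_compartments: 2
theta:        # typical values at FFM = 56 kg, age = 22.5 y
  CL: 0.210   # L/h
  V1: 2.85    # L
  Q: 0.160    # L/h
  V2: 0.55    # L
covariate_relations:
  - {parameter: CL, covariate: ffm, form: power, reference_value: 56.0, value: 1.0}
  - {parameter: CL, covariate: age, form: linear, reference_value: 22.5, value: -0.005}
  - {parameter: V1, covariate: ffm, form: power, reference_value: 56.0, value: 1.0}
  - {parameter: Q,  covariate: ffm, form: power, reference_value: 56.0, value: 1.0}
  - {parameter: V2, covariate: ffm, form: power, reference_value: 56.0, value: 1.0}
omega_params: [CL, V1]
omega:        # sd(lnCL)=0.30, sd(lnV1)=0.21, corr 0.45
  - [0.0900, 0.0284]
  - [0.0284, 0.0441]
sigma_prop: 0.20    # proportional residual SD (fraction, one-stage assay)
sigma_add: 0.002
lloq: 0.01
provenance: reconstructed (see header comment)
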