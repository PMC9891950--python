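# SCORE2 10-year CVD (fatal + non-fatal) risk equation.
# Log-hazard-ratio terms on centred/scaled covariates, per sex, with
# age-interaction terms, and the 10-year baseline survival S0.
# Source: ESC 2021 SCORE2 working group publication; packaged as editable
# configuration so regional or updated coefficient sets can be swapped in.
model: SCORE2
endpoint: 10-year fatal and non-fatal cardiovascular disease
transforms:
  age: {center: 60.0, scale: 5.0}
  sbp: {center: 120.0, scale: 20.0}
  tc: {center: 6.0, scale: 1.0}
  hdl: {center: 1.3, scale: 0.5}
male:
  s0_10yr: 0.9605
  coefficients:
    cage: 0.3742
    smoking: 0.6012
    csbp: 0.2777
    ctc: 0.1458
    chdl: -0.2698
    smoking_x_cage: -0.0755
    csbp_x_cage: -0.0255
    ctc_x_cage: -0.0281
    chdl_x_cage: 0.0426
female:
  s0_10yr: 0.9776
  coefficients:
    cage: 0.4648
    smoking: 0.7744
    csbp: 0.3131
    ctc: 0.1002
    chdl: -0.2606
    smoking_x_cage: -0.1088
    csbp_x_cage: -0.0277
    ctc_x_cage: -0.0226
    chdl_x_cage: 0.0613
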