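# SCORE 10-year fatal-CVD risk equation (Weibull cause-specific form,
# CHD and non-CHD components), with low- and high-risk region calibrations.
# Cause-specific survival: S(a) = exp(-exp(alpha) * (a - 20)^p); linear
# predictor w = b_chol*(TC-6) + b_sbp*(SBP-120) + b_smoking*smoker applied
# as S^exp(w); 10-year risk = 1 - S(age+10)/S(age) per cause, summed.
model: SCORE
endpoint: 10-year fatal cardiovascular disease
betas:
  chd: {smoking: 0.71, chol: 0.24, sbp: 0.018}
  non_chd: {smoking: 0.63, chol: 0.02, sbp: 0.022}
regions:
  low:
    chd:
      male: {alpha: -22.1, p: 4.71}
      female: {alpha: -29.8, p: 6.36}
    non_chd:
      male: {alpha: -26.7, p: 5.64}
      female: {alpha: -31.0, p: 6.62}
  high:
    chd:
      male: {alpha: -21.0, p: 4.62}
      female: {alpha: -28.7, p: 6.23}
    non_chd:
      male: {alpha: -25.7, p: 5.47}
      female: {alpha: -30.0, p: 6.42}
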