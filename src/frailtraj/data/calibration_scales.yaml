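# SCORE2 regional recalibration: four clusters of countries by CVD risk.
# Calibrated risk = 1 - exp(-exp(scale1 + scale2 * ln(-ln(1 - r)))) with r
# the uncalibrated risk. United Kingdom -> low; United States -> high.
low:
  male: {scale1: -0.5699, scale2: 0.7476}
  female: {scale1: -0.7380, scale2: 0.7019}
moderate:
  male: {scale1: -0.1565, scale2: 0.8009}
  female: {scale1: -0.3143, scale2: 0.7701}
high:
  male: {scale1: 0.3207, scale2: 0.9360}
  female: {scale1: 0.5710, scale2: 0.9369}
very_high:
  male: {scale1: 0.5836, scale2: 0.8294}
  female: {scale1: 0.9412, scale2: 0.8329}
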