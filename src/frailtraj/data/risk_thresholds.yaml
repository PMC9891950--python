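# ESC three-category classification of 10-year CVD risk (percent), by age
# band.  Within a band: risk < cut1 -> low_to_moderate; cut1 <= risk < cut2
# -> high; risk >= cut2 -> very_high (boundary values go to the higher
# category; intervals are left-closed at the top).
age_bands:
  - {min_age: 40, max_age: 49, cut1: 2.5, cut2: 7.5}
  - {min_age: 50, max_age: 69, cut1: 5.0, cut2: 10.0}
  - {min_age: 70, max_age: null, cut1: 7.5, cut2: 15.0}
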