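# Photographic Figure Rating Scale: BMI of the 10 silhouette photographs,
# ordered from the most emaciated to the most obese.  Approximate published
# values; editable.
silhouette_bmi:
  - 12.51
  - 14.72
  - 16.65
  - 17.57
  - 20.33
  - 23.09
  - 26.16
  - 29.26
  - 35.92
  - 41.23
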