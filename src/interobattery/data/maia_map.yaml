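# MAIA (32 items, 8 subscales), published v1 assignment.
# Items 5-9 are reverse-coded; responses on a 0-5 scale; subscale = item mean.
instrument: MAIA
response_range: [0, 5]
aggregation: mean
reverse: [5, 6, 7, 8, 9]
items:
  1: maia_m1
  2: maia_m1
  3: maia_m1
  4: maia_m1
  5: maia_m2
  6: maia_m2
  7: maia_m2
  8: maia_m3
  9: maia_m3
  10: maia_m3
  11: maia_m4
  12: maia_m4
  13: maia_m4
  14: maia_m4
  15: maia_m4
  16: maia_m4
  17: maia_m4
  18: maia_m5
  19: maia_m5
  20: maia_m5
  21: maia_m5
  22: maia_m5
  23: maia_m6
  24: maia_m6
  25: maia_m6
  26: maia_m6
  27: maia_m7
  28: maia_m7
  29: maia_m7
  30: maia_m8
  31: maia_m8
  32: maia_m8
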