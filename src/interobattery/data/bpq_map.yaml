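# BPQ-22 three-factor map: body awareness (BOA), supradiaphragmatic (SUP),
# subdiaphragmatic/body awareness (BOA/SUB).  The exact published item->factor
# assignment is not bundled with this package; the block assignment below is a
# documented editable default — replace it with the published table for real
# scoring.  Responses on a 1-5 scale; subscale = item sum.
instrument: BPQ
response_range: [1, 5]
aggregation: sum
reverse: []
items:
  1: bpq_boa
  2: bpq_boa
  3: bpq_boa
  4: bpq_boa
  5: bpq_boa
  6: bpq_boa
  7: bpq_boa
  8: bpq_boa
  9: bpq_boa
  10: bpq_boa
  11: bpq_boa
  12: bpq_boa
  13: bpq_sup
  14: bpq_sup
  15: bpq_sup
  16: bpq_sup
  17: bpq_sup
  18: bpq_boa_sub
  19: bpq_boa_sub
  20: bpq_boa_sub
  21: bpq_boa_sub
  22: bpq_boa_sub
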