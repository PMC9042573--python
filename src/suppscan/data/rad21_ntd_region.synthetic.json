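{
  "protein_name": "Rad21-NTD",
  "start": 18,
  "end": 87,
  "wt_sequence": "WLEAVADTNQIGLSELVTDTNQSGHSEKVADTNQIALRLKVQLTLQIGLIEKVADTYLLGLSEKVADTNK"
}
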