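{
  "protein_name": "Psm3-HCJ",
  "start": 95,
  "end": 168,
  "wt_sequence": "ESEKVADTNQKKLSEKLADTNVIGLSVKVLLESAGGLSEKVADTNQIGLSEKVADTNQIGLSEKVADTNGIGLY"
}
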