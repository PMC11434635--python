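{
  "options": [
    {"name": "grilled chicken salad",
     "levels": {"GC": "high", "ND": "high", "P": "moderate", "C": "moderate"}},
    {"name": "white pasta alfredo",
     "levels": {"GC": "low", "ND": "low", "P": "high", "C": "high"}}
  ]
}
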