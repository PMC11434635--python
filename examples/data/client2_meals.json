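{
  "options": [
    {"name": "kale and quinoa salad",
     "levels": {"BPM": "high", "BH": "high", "F": "moderate", "EP": "high"}},
    {"name": "canned vegetable soup",
     "levels": {"BPM": "low", "BH": "moderate", "F": "moderate", "EP": "high"}}
  ]
}
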