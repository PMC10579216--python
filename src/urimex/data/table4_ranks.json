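{
  "description": "Published per-criterion ranks comparing urease-treated, urease-non-treated and water-treated samples (all heated).",
  "criteria": ["repeatability", "coverage", "recovery"],
  "ranks": {
    "Urease-treated samples (UT-H)": [3, 3, 3],
    "Urease-non-treated samples (NT-H)": [2, 2, 2],
    "Water-treated samples (WT-H)": [1, 1, 1]
  },
  "printed_cumulative": {
    "Urease-treated samples (UT-H)": 9,
    "Urease-non-treated samples (NT-H)": 6,
    "Water-treated samples (WT-H)": 3
  }
}
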