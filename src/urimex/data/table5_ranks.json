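{
  "description": "Published per-criterion ranks comparing heating versus sonication during urease pre-treatment.",
  "criteria": ["repeatability", "coverage", "recovery"],
  "ranks": {
    "Urease-treated: Heating (UT-H)": [4, 4, 4],
    "Urease-treated: Sonicate (UT-S)": [2, 3, 2],
    "Urease-non-treated: Heating (NT-H)": [1, 2, 3],
    "Urease-non-treated: Sonicate (NT-S)": [3, 1, 1]
  },
  "printed_cumulative": {
    "Urease-treated: Heating (UT-H)": 12,
    "Urease-treated: Sonicate (UT-S)": 7,
    "Urease-non-treated: Heating (NT-H)": 6,
    "Urease-non-treated: Sonicate (NT-S)": 5
  }
}
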