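{
  "description": "Published per-criterion ranks for the five extraction methods (Part A). Rank 1 is best; the cumulative score is the rank sum.",
  "criteria": ["repeatability", "coverage", "recovery"],
  "ranks": {
    "Method 1 (original in-house)": [4, 5, 4],
    "Method 2 (acetonitrile addition)": [5, 2, 2],
    "Method 3 (two-step derivatization)": [2, 4, 5],
    "Method 4 (combination of Methods 2 & 3)": [3, 3, 3],
    "Method 5 (direct analysis)": [1, 1, 1]
  },
  "printed_cumulative": {
    "Method 1 (original in-house)": 13,
    "Method 2 (acetonitrile addition)": 9,
    "Method 3 (two-step derivatization)": 11,
    "Method 4 (combination of Methods 2 & 3)": 9,
    "Method 5 (direct analysis)": 3
  }
}
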