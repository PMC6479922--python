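{
  "description": "Published per-exercise TP/FN/FP/TN decision counts for the union exercise (per-second middle-section decisions). Input data for the verification-scheme rates.",
  "counts": {
    "A": {"tp": 15, "fn": 4, "fp": 0, "tn": 1},
    "B": {"tp": 15, "fn": 1, "fp": 0, "tn": 4},
    "C": {"tp": 5, "fn": 0, "fp": 6, "tn": 9},
    "D": {"tp": 15, "fn": 4, "fp": 1, "tn": 0},
    "E": {"tp": 7, "fn": 6, "fp": 0, "tn": 7}
  }
}
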