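{
  "_comment": "Per-metric TP/FP/TN/FN patient counts, derived-from-printed-values: recovered algebraically from the published sensitivity/specificity/accuracy/likelihood-ratio statistics and their Wilson CIs for the 15-patient cohort; the counts themselves were not printed. Note the implied favorable/unfavorable splits differ between metrics (si, dcin: 10/5; dc, dcout: 9/6) in the source material; they are kept verbatim.",
  "si": {"tp": 6, "fp": 1, "tn": 4, "fn": 4},
  "dcout": {"tp": 5, "fp": 1, "tn": 5, "fn": 4},
  "dc": {"tp": 5, "fp": 1, "tn": 5, "fn": 4},
  "dcin": {"tp": 4, "fp": 1, "tn": 4, "fn": 6},
  "engel_classes": {"I": 10, "II": 2, "IV": 3}
}
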