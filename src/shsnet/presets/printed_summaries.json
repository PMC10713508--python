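{
  "description": "Published cohort-level summary statistics of the SHSQ-25 study (group means/SDs of demographic and anthropometric variables, gender counts, per-domain node predictability, item-network edge counts). These printed numbers serve as inputs for recomputing derived quantities.",
  "group_n": {"optimal": 106, "suboptimal": 111},
  "numeric_variables": {
    "age":   {"optimal": [53.09, 7.57],  "suboptimal": [57.02, 10.43], "printed_p": 0.002, "printed_d": 0.43, "printed_label": "medium"},
    "bmi":   {"optimal": [25.67, 4.78],  "suboptimal": [25.56, 5.04],  "printed_p": 0.869, "printed_d": 0.02, "printed_label": "small"},
    "sbp":   {"optimal": [142.06, 22.86], "suboptimal": [149.70, 25.31], "printed_p": 0.021, "printed_d": 0.32, "printed_label": "small"},
    "dbp":   {"optimal": [82.52, 12.99], "suboptimal": [86.58, 15.54], "printed_p": 0.038, "printed_d": 0.28, "printed_label": "small"},
    "height": {"optimal": [1.64, 0.07],  "suboptimal": [1.61, 0.07],   "printed_p": 0.837, "printed_d": 0.03, "printed_label": "small"},
    "weight": {"optimal": [68.70, 12.78], "suboptimal": [66.49, 14.40], "printed_p": 0.234, "printed_d": 0.16, "printed_label": "small"},
    "waist": {"optimal": [89.72, 12.57], "suboptimal": [90.86, 12.95], "printed_p": 0.512, "printed_d": 0.09, "printed_label": "small"},
    "hip":   {"optimal": [101.22, 10.82], "suboptimal": [101.20, 10.91], "printed_p": 0.989, "printed_d": 0.002, "printed_label": "small"},
    "whtr":  {"optimal": [0.55, 0.08],   "suboptimal": [0.56, 0.08],   "printed_p": 0.358, "printed_d": 0.13, "printed_label": "small"}
  },
  "gender_counts": {"optimal": {"female": 59, "male": 47}, "suboptimal": {"female": 74, "male": 37}},
  "domain_predictability": {
    "optimal":    {"FT": 0.61, "CS": 0.78, "DS": 0.67, "IS": 0.56, "MH": 0.48},
    "suboptimal": {"FT": 0.81, "CS": 0.68, "DS": 0.74, "IS": 0.64, "MH": 0.39}
  },
  "item_network_edges": {"optimal": 58, "suboptimal": 43, "nodes": 25}
}
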