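{
  "description": "Published per-item response summaries (mean, SD on the 0-4 scale) for the optimal and suboptimal SHSQ-25 study populations; calibration targets for the synthetic cohort generator.",
  "n": {"optimal": 106, "suboptimal": 111},
  "items": {
    "CS1": {"optimal": [0.11, 0.37], "suboptimal": [0.94, 0.85]},
    "CS2": {"optimal": [0.10, 0.36], "suboptimal": [1.13, 1.10]},
    "CS3": {"optimal": [0.37, 0.81], "suboptimal": [1.59, 1.23]},
    "DS1": {"optimal": [0.14, 0.52], "suboptimal": [0.75, 0.97]},
    "DS2": {"optimal": [0.28, 0.77], "suboptimal": [1.23, 1.15]},
    "DS3": {"optimal": [0.23, 0.63], "suboptimal": [0.96, 1.04]},
    "FT1": {"optimal": [0.64, 1.01], "suboptimal": [2.20, 1.07]},
    "FT2": {"optimal": [0.34, 0.59], "suboptimal": [1.32, 0.95]},
    "FT3": {"optimal": [0.34, 0.65], "suboptimal": [1.26, 0.91]},
    "FT4": {"optimal": [0.75, 0.96], "suboptimal": [2.14, 1.28]},
    "FT5": {"optimal": [0.28, 0.58], "suboptimal": [1.52, 1.24]},
    "FT6": {"optimal": [0.37, 0.72], "suboptimal": [1.58, 1.17]},
    "FT7": {"optimal": [1.02, 1.15], "suboptimal": [2.10, 1.03]},
    "FT8": {"optimal": [0.79, 1.03], "suboptimal": [2.14, 0.90]},
    "FT9": {"optimal": [0.42, 0.77], "suboptimal": [1.60, 1.22]},
    "IS1": {"optimal": [0.15, 0.39], "suboptimal": [1.15, 0.96]},
    "IS2": {"optimal": [0.51, 0.81], "suboptimal": [1.43, 1.10]},
    "IS3": {"optimal": [0.22, 0.57], "suboptimal": [1.17, 1.17]},
    "MH1": {"optimal": [0.39, 0.85], "suboptimal": [0.98, 1.14]},
    "MH2": {"optimal": [0.29, 0.65], "suboptimal": [1.19, 1.11]},
    "MH3": {"optimal": [1.15, 1.21], "suboptimal": [2.07, 1.25]},
    "MH4": {"optimal": [0.42, 0.63], "suboptimal": [1.14, 0.89]},
    "MH5": {"optimal": [0.43, 0.76], "suboptimal": [1.17, 0.99]},
    "MH6": {"optimal": [0.33, 0.69], "suboptimal": [1.06, 1.02]},
    "MH7": {"optimal": [0.34, 0.80], "suboptimal": [1.37, 1.30]}
  }
}
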