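{
  "CYP2D6": {
    "type": "activity_score",
    "order": ["Poor", "Intermediate", "Normal", "Ultrarapid"],
    "bins": [
      {"category": "Poor", "min": 0, "max": 0},
      {"category": "Intermediate", "min": 0, "max": 1.25, "min_open": true, "max_open": true},
      {"category": "Normal", "min": 1.25, "max": 2.25},
      {"category": "Ultrarapid", "min": 2.25, "max": 100, "min_open": true}
    ]
  },
  "CYP2C9": {
    "type": "activity_score",
    "order": ["Poor", "Intermediate (AS 1.0)", "Intermediate (AS 1.5)", "Normal"],
    "bins": [
      {"category": "Poor", "min": 0, "max": 0.5},
      {"category": "Intermediate (AS 1.0)", "min": 1, "max": 1},
      {"category": "Intermediate (AS 1.5)", "min": 1.5, "max": 1.5},
      {"category": "Normal", "min": 2, "max": 2}
    ]
  },
  "DPYD": {
    "type": "activity_score",
    "order": ["Poor (AS 0)", "Poor (AS 0.5)", "Intermediate (AS 1)", "Intermediate (AS 1.5)", "Normal"],
    "bins": [
      {"category": "Poor (AS 0)", "min": 0, "max": 0},
      {"category": "Poor (AS 0.5)", "min": 0.5, "max": 0.5},
      {"category": "Intermediate (AS 1)", "min": 1, "max": 1},
      {"category": "Intermediate (AS 1.5)", "min": 1.5, "max": 1.5},
      {"category": "Normal", "min": 2, "max": 2}
    ]
  },
  "CYP2C19": {
    "type": "function_pairs",
    "order": ["Poor", "Intermediate", "Normal", "Rapid", "Ultrarapid"],
    "pairs": {
      "increased|increased": "Ultrarapid",
      "increased|normal": "Rapid",
      "normal|normal": "Normal",
      "increased|no_function": "Intermediate",
      "no_function|normal": "Intermediate",
      "no_function|no_function": "Poor"
    }
  },
  "NUDT15": {
    "type": "function_pairs",
    "order": ["Poor", "Intermediate", "Normal"],
    "pairs": {
      "normal|normal": "Normal",
      "no_function|normal": "Intermediate",
      "no_function|no_function": "Poor"
    }
  },
  "TPMT": {
    "type": "function_pairs",
    "order": ["Poor", "Intermediate", "Normal"],
    "pairs": {
      "normal|normal": "Normal",
      "no_function|normal": "Intermediate",
      "no_function|no_function": "Poor"
    }
  },
  "SLCO1B1": {
    "type": "function_pairs",
    "order": ["Poor", "Decreased", "Normal"],
    "pairs": {
      "normal|normal": "Normal",
      "decreased|normal": "Decreased",
      "decreased|decreased": "Poor"
    }
  },
  "UGT1A1": {
    "type": "function_pairs",
    "order": ["Poor", "Intermediate", "Normal"],
    "pairs": {
      "normal|normal": "Normal",
      "decreased|normal": "Intermediate",
      "decreased|decreased": "Poor"
    }
  }
}
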