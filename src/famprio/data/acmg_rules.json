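{
  "comment": "ACMG/AMP 2015 evidence-combining rules. Each rule lists minimum counts per evidence strength; a classification applies when any of its rules is satisfied. Conflicting pathogenic- and benign-side matches yield VUS.",
  "pathogenic": [
    {"pvs": 1, "ps": 1},
    {"pvs": 1, "pm": 2},
    {"pvs": 1, "pm": 1, "pp": 1},
    {"pvs": 1, "pp": 2},
    {"ps": 2},
    {"ps": 1, "pm": 3},
    {"ps": 1, "pm": 2, "pp": 2},
    {"ps": 1, "pm": 1, "pp": 4}
  ],
  "likely_pathogenic": [
    {"pvs": 1, "pm": 1},
    {"ps": 1, "pm": 1},
    {"ps": 1, "pp": 2},
    {"pm": 3},
    {"pm": 2, "pp": 2},
    {"pm": 1, "pp": 4}
  ],
  "benign": [
    {"ba": 1},
    {"bs": 2}
  ],
  "likely_benign": [
    {"bs": 1, "bp": 1},
    {"bp": 2}
  ]
}
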