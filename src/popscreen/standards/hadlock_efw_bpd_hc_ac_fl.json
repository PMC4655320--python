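{
  "name": "hadlock_efw_bpd_hc_ac_fl",
  "kind": "efw_equation",
  "citation": "Hadlock FP, Harrist RB, Sharman RS, Deter RL, Park SK. Estimation of fetal weight with the use of head, body, and femur measurements - a prospective study. Am J Obstet Gynecol 1985;151:333-337. Transcription: verify against cited reference.",
  "comment": "log10(weight in g) as a polynomial in BPD, HC, AC, FL (cm). Four-parameter model.",
  "required": ["bpd_cm", "hc_cm", "ac_cm", "fl_cm"],
  "intercept": 1.3596,
  "terms": [
    {"coef": 0.0064, "vars": ["hc_cm"]},
    {"coef": 0.0424, "vars": ["ac_cm"]},
    {"coef": 0.174, "vars": ["fl_cm"]},
    {"coef": 0.00061, "vars": ["bpd_cm", "ac_cm"]},
    {"coef": -0.00386, "vars": ["ac_cm", "fl_cm"]}
  ]
}
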