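{
  "name": "customisation_surrogate",
  "kind": "customised_efw",
  "citation": "Simplified customisation surrogate (this package). Illustrative linear offsets for maternal height, booking weight and ethnicity around a term optimal weight; NOT the proprietary GROW coefficient set.",
  "comment": "Term optimal weight (g) = base + h*(height_cm - 163) + w*(weight_kg - 64) + ethnicity offset. Fetal-weight proportion-of-term curve shares the Hadlock weight-for-GA shape; percentile from a proportional-SD normal model.",
  "base_term_weight_g": 3480.0,
  "height_coef_g_per_cm": 8.0,
  "weight_coef_g_per_kg": 7.5,
  "ethnicity_offsets_g": {"white": 0.0, "south_asian": -180.0, "black": -120.0, "east_asian": -150.0, "other": -60.0},
  "proportion_curve": {"type": "hadlock_normalised", "coefficients": [0.578, 0.332, -0.00354], "term_ga": 40.0},
  "cv": 0.11
}
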