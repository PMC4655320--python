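{
  "name": "hadlock_weight_for_ga",
  "kind": "efw_for_ga",
  "citation": "Hadlock FP, Harrist RB, Martinez-Poyer J. In utero analysis of fetal growth: a sonographic weight standard. Radiology 1991;181:129-133. Transcription: verify against cited reference.",
  "comment": "Median weight ln(g) = 0.578 + 0.332*GA - 0.00354*GA^2; SD proportional to the median (12.7%), percentiles on the natural scale.",
  "working_scale": "natural",
  "ga_domain": [14.0, 42.0],
  "location": {"type": "exp_poly", "coefficients": [0.578, 0.332, -0.00354]},
  "scale": {"type": "proportional", "fraction": 0.127}
}
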