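{
  "name": "short_metatarsal",
  "description": "Short first metatarsal; with diminished ground-reactive force the center of rotation shows little normal frontal or transverse excursion.",
  "transform": [{"op": "scale", "path": "head.shaft_length", "factor": 0.85}],
  "predicted_displacement": "none",
  "predicted_mobility": "none"
}
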