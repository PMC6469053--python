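{
  "name": "rounded_edge",
  "description": "Rounded distal metatarsal edge with diminished radius (hallux abducto valgus risk morphology).",
  "transform": [{"op": "scale_head_radius", "factor": 0.8}],
  "predicted_displacement": "distal",
  "predicted_mobility": "increased-frontal"
}
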