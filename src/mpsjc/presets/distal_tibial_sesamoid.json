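{
  "name": "distal_tibial_sesamoid",
  "description": "Tibial sesamoid positioned more distal than usual, tilting the transverse joint axis oblique to the long axis.",
  "transform": [{"op": "translate_sesamoid", "label": "tibial", "dx": 1.0}],
  "predicted_displacement": "lateral-proximal",
  "predicted_mobility": "none"
}
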