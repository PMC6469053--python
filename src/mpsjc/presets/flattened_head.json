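{
  "name": "flattened_head",
  "description": "Flattened distal articular surface keeping phalanx and metatarsal aligned in the sagittal plane (hallux limitus / rigidus morphology).",
  "transform": [{"op": "set", "path": "head.distal_flattening", "value": 0.06}],
  "predicted_displacement": "none",
  "predicted_mobility": "restricted-sagittal"
}
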