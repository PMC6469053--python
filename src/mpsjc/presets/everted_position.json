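{
  "name": "everted_position",
  "description": "Metatarsal held in an everted (pronated) position; the sesamoid apparatus swings medial relative to the bone.",
  "transform": [{"op": "rotate_sesamoids_frontal", "angle_deg": 8.0}],
  "predicted_displacement": "medial-plantar",
  "predicted_mobility": "none"
}
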