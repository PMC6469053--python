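{
  "name": "proximal_sesamoids",
  "description": "Both sesamoids seated 16 deg more proximal around the head relative to the distal metatarsal edge (hallux limitus / rigidus risk morphology); groove engagement is pushed toward end-range.",
  "transform": [
    {
      "op": "rotate_sesamoids_arc",
      "angle_deg": -16.0
    }
  ],
  "predicted_displacement": "proximal",
  "predicted_mobility": "none"
}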