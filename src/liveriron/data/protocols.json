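{
  "me-gre": {
    "name": "me-gre",
    "initial_te_ms": 0.99,
    "delta_te_ms": 1.41,
    "n_echoes": 12,
    "field_strength": 1.5,
    "extras": {
      "tr_ms": 200.0,
      "flip_angle_deg": 20.0,
      "bandwidth_hz_per_px": 1955.0,
      "acceleration": null,
      "acquisition": "2D",
      "fat_suppression": "CHESS",
      "slices": 2
    }
  },
  "qdixon": {
    "name": "qdixon",
    "initial_te_ms": 2.38,
    "delta_te_ms": 2.38,
    "n_echoes": 6,
    "field_strength": 1.5,
    "extras": {
      "tr_ms": 15.6,
      "flip_angle_deg": 4.0,
      "bandwidth_hz_per_px": 1080.0,
      "acceleration": 4,
      "acquisition": "3D",
      "fat_suppression": "Dixon",
      "slices": 64
    }
  },
  "qdixon-wip": {
    "name": "qdixon-wip",
    "initial_te_ms": 1.04,
    "delta_te_ms": 1.17,
    "n_echoes": 6,
    "field_strength": 1.5,
    "extras": {
      "tr_ms": 9.0,
      "flip_angle_deg": 4.0,
      "bandwidth_hz_per_px": 1080.0,
      "acceleration": 3,
      "acquisition": "3D",
      "fat_suppression": "Dixon",
      "slices": 80
    }
  }
}
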