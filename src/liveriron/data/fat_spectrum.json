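{
  "name": "liver-6peak",
  "description": "Six-peak liver triglyceride spectrum; chemical shifts relative to water at 1.5 T conventions, relative amplitudes normalized to sum to 1. Swappable: vendor spectra differ slightly.",
  "peaks": [
    {"shift_ppm": -3.80, "amplitude": 0.088},
    {"shift_ppm": -3.40, "amplitude": 0.694},
    {"shift_ppm": -2.60, "amplitude": 0.128},
    {"shift_ppm": -1.94, "amplitude": 0.004},
    {"shift_ppm": -0.39, "amplitude": 0.039},
    {"shift_ppm": 0.60, "amplitude": 0.047}
  ]
}
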