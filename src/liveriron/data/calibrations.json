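{
  "henninger": {
    "slope": 0.436,
    "intercept": 4.964,
    "label": "henninger",
    "source": "biopsy-calibrated 2D ME-GRE R2* relaxometry at 1.5 T"
  },
  "wood": {
    "slope": 0.455,
    "intercept": -3.617,
    "label": "wood",
    "source": "published R2*-LIC calibration (Wood)"
  },
  "garbowski": {
    "slope": 0.573,
    "intercept": -2.507,
    "label": "garbowski",
    "source": "published R2*-LIC calibration (Garbowski)"
  },
  "hankins": {
    "slope": 0.502,
    "intercept": -8.145,
    "label": "hankins",
    "source": "published R2*-LIC calibration (Hankins)"
  },
  "qdixon-cross": {
    "slope": 0.434,
    "intercept": 6.135,
    "label": "qdixon-cross",
    "source": "cross-calibration of the ME-GRE equation onto qDixon R2*"
  },
  "qdixon-wip-cross": {
    "slope": 0.429,
    "intercept": 5.682,
    "label": "qdixon-wip-cross",
    "source": "cross-calibration of the ME-GRE equation onto qDixon-WIP R2*"
  }
}
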