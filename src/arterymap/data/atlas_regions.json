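{
  "comment": "Region atlas calibration: spherical regions per artery, built from affine combinations of 68-point landmarks. Weights are given for the subject's LEFT side using left-side landmark indices; right-side regions are derived by the scheme's mirror index map. Radii are fractions of the outer-interocular span (distance between landmarks 36 and 45).",
  "version": 1,
  "scale_pair": [36, 45],
  "regions": {
    "Fa":  {"weights": {"11": 0.34, "54": 0.33, "35": 0.33}, "radius_frac": 0.45},
    "IL":  {"weights": {"56": 0.65, "9": 0.35},              "radius_frac": 0.18},
    "SL":  {"weights": {"52": 0.65, "35": 0.35},             "radius_frac": 0.16},
    "Ang": {"weights": {"35": 0.5, "42": 0.5},               "radius_frac": 0.18},
    "LN":  {"weights": {"35": 0.7, "29": 0.3},               "radius_frac": 0.14},
    "DN":  {"weights": {"28": 0.75, "42": 0.25},             "radius_frac": 0.14},
    "STr": {"weights": {"22": 1.0},                          "radius_frac": 0.13},
    "SO":  {"weights": {"24": 1.0},                          "radius_frac": 0.13},
    "ST":  {"weights": {"16": 0.45, "45": 0.35, "26": 0.2},  "radius_frac": 0.28}
  }
}
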