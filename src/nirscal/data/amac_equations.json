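{
  "version": 1,
  "description": "Published sqrt-scale calibration coefficients relating ammonium-acetate-extractable concentration to total content, per element: sqrt(total) = slope * sqrt(amac) + intercept (both in g/L substrate).",
  "equations": {
    "P":  {"slope": 1.22, "intercept": 2.23},
    "K":  {"slope": 0.93, "intercept": 1.80},
    "Ca": {"slope": 1.45, "intercept": -8.60},
    "Mg": {"slope": 1.53, "intercept": -4.40}
  }
}
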