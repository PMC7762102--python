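{
  "description": "Hemoglobin extinction coefficients (Gratzer/Prahl compilation) and the general age/wavelength differential-pathlength-factor equation (Scholkmann & Wolf 2013).",
  "extinction_units": "mm^-1 uM^-1",
  "extinction": {
    "690": {"o2hb": 2.761e-05, "hhb": 2.05196e-04},
    "830": {"o2hb": 9.740e-05, "hhb": 6.9304e-05}
  },
  "dpf_model": "dpf = a + b * age**c + d * lambda_nm**3 + e * lambda_nm**2 + f * lambda_nm",
  "dpf_coefficients": {
    "a": 223.3,
    "b": 0.05624,
    "c": 0.8493,
    "d": -5.723e-07,
    "e": 0.001245,
    "f": -0.9025
  }
}
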