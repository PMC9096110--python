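{
  "comF": {
    "name": "comF",
    "intercept": 0.8634,
    "coefficients": {
      "tscales4": -0.157,
      "CTDC19": -0.154,
      "protFP6": -0.135,
      "CTDC21": 0.133,
      "fasgai4": -0.132,
      "mswhimscore1": 0.122,
      "hydrophobicity": -0.12
    }
  },
  "comF2": {
    "name": "comF2",
    "intercept": 0.1786,
    "coefficients": {
      "APAAC1_15": 0.1522,
      "CTDC10": -2.2951,
      "CTDC19": -0.6069,
      "CTDD49": -0.0065,
      "QSO19": 0.2176,
      "fasgai4": 0.9747,
      "protFP3": 0.3691,
      "Pse_PC13": 2.0823
    }
  }
}
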