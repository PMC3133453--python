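{
  "comment": "Reference trained-network weight tables for the 6-7-1 dipeptide QSAR net. Hidden-to-output weights (lw) and input-to-hidden weights (iw, rows = hidden neurons, columns = Z11,Z12,Z13,Z21,Z22,Z23). The bias values are unknown and set to zero, so this fixture supports the connection-weight interpretation procedure only; it is NOT a usable predictor.",
  "input_size": 6,
  "hidden_size": 7,
  "iw": [
    [-0.3515, 0.28331, 0.28286, -0.44043, 0.037431, -0.085447],
    [0.27249, 0.041643, -0.9822, -0.087255, 0.47412, -0.18318],
    [0.57416, -0.14092, 0.60775, -0.08924, 0.11108, -0.5922],
    [0.24392, 0.21597, -0.20115, 0.24221, -0.07429, -0.54316],
    [0.23817, 0.07212, 0.68217, -0.00285, 0.26846, -0.47522],
    [-0.30588, 0.21639, 0.036361, -0.41676, -0.2514, -0.23479],
    [-0.090315, -0.058403, 0.0745, -0.32458, -0.24483, -0.10795]
  ],
  "b1": [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
  "lw": [0.70466, 0.74384, -0.63652, -0.37093, 0.49303, -1.3532, 1.1885],
  "b2": 0.0,
  "hidden_transfer": "tansig",
  "output_transfer": "purelin"
}
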