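{
  "comment": "Default steady-state channel activation means (volts) for the five gesture classes on six envelope channels. Hand-chosen once: Rest sits near the sensor baseline; each grasp loads a distinct subset of flexor/extensor channels, mimicking the per-gesture activation patterns of a six-sensor forearm bracelet.",
  "gesture_names": ["Rest", "Spherical", "Tip", "Platform", "Point"],
  "mean_activation": [
    [0.30, 0.30, 0.30, 0.30, 0.30, 0.30],
    [2.80, 2.20, 1.20, 0.60, 0.50, 1.50],
    [1.00, 2.60, 2.40, 0.80, 0.40, 0.60],
    [0.50, 0.80, 1.50, 2.90, 2.50, 1.00],
    [0.80, 0.50, 2.00, 1.00, 1.80, 2.70]
  ],
  "within_rep_jitter": 0.10,
  "noise_sd": 0.25,
  "noise_bandwidth": 10.0,
  "separability": 1.0
}
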