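{
  "center_frequency_hz": 50000000.0,
  "element_diameter_m": 0.005,
  "focal_distance_m": 0.004,
  "sound_speed_m_s": 1500.0,
  "voltage_pressure_table": [
    [0.0, 0.0],
    [4.74, 0.234],
    [9.48, 0.431],
    [14.22, 0.627],
    [18.96, 0.824],
    [23.7, 1.0]
  ]
}
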