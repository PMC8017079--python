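{
  "data": {
    "I_DC": 0.0,
    "pulses": [
      {
        "E_rev": null,
        "amplitude": -500.0,
        "kind": "ideal_current",
        "t_end": 0.8,
        "t_start": 0.5
      }
    ]
  },
  "kind": "stimulus_protocol",
  "schema": 1
}
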