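{
  "data": {
    "I_DC": 37.0,
    "pulses": []
  },
  "kind": "stimulus_protocol",
  "schema": 1
}
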