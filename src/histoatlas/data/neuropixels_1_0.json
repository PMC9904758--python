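{
  "name": "neuropixels-1.0-like",
  "n_channels": 384,
  "channel_pitch_um": 20.0,
  "tip_length_um": 175.0,
  "first_channel_offset_um": 0.0,
  "n_shanks": 1,
  "shank_spacing_um": 0.0
}
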