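# Enclosed room: continuous bright hard surfaces, no gaps, rare second returns.
scene: room
config:
  half_width_x: 4.0
  half_width_y: 5.0
  ceiling_height: 2.0
  floor_depth: 1.3
  reflectance_mean: 0.75
  reflectance_sd: 0.05
  range_noise_sd_m: 0.05
  second_return_prob: 0.01
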