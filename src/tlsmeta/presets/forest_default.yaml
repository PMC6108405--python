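# Generic forest stand: fragmented canopy with gaps, sparse understory,
# darker foliage, frequent partial interceptions (second returns).
scene: forest
config:
  canopy_base_height: 12.0
  canopy_top_height: 18.0
  canopy_gap_prob: 0.25
  understory_density: 0.05
  trunk_count: 12
  trunk_radius: 0.25
  stand_radius: 30.0
  second_return_prob: 0.25
  reflectance_mean: 0.35
  reflectance_sd: 0.08
  range_noise_sd_m: 0.05
  max_range_clip: 40.0
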