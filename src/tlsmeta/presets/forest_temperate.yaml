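# Temperate forest variant: higher, more open canopy, sparser understory,
# brighter foliage at 905 nm. Illustrative, not calibrated to any site.
scene: forest
config:
  canopy_base_height: 16.0
  canopy_top_height: 24.0
  canopy_gap_prob: 0.35
  understory_density: 0.02
  trunk_count: 10
  trunk_radius: 0.30
  stand_radius: 30.0
  second_return_prob: 0.20
  reflectance_mean: 0.45
  reflectance_sd: 0.08
  range_noise_sd_m: 0.05
  max_range_clip: 40.0
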