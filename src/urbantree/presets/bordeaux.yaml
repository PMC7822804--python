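# Open green square: unsealed surface, deeper soil, windier.
# Tree morphology is the site mean for mature Tilia cordata.
site:
  latitude: 48.13
  longitude: 11.58
  sensor_height: 20.0
  tree_height: 15.12
  utc_offset: 1.0
tree:
  lai: 2.41
  canopy_cover: 67.12
  height: 15.12
  dbh: 29.18
soil:
  layer_thickness: [0.2, 0.3, 0.5]
  runoff_fraction: 0.0
initial_rwc: 0.9
forcing:
  synthetic:
    preset: munich_summer
    wind_mean: 0.9
    seed: 42
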