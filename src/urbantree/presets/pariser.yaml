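# Sealed paved square: 40% runoff, thinner soil layers, calmer.
site:
  latitude: 48.13
  longitude: 11.58
  sensor_height: 20.0
  tree_height: 16.78
  utc_offset: 1.0
tree:
  lai: 2.54
  canopy_cover: 81.7
  height: 16.78
  dbh: 44.68
soil:
  layer_thickness: [0.1, 0.2, 0.4]
  runoff_fraction: 0.4
initial_rwc: 0.9
forcing:
  synthetic:
    preset: munich_summer
    wind_mean: 0.5
    seed: 42
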