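# Test case 2 control arm: poplar leaves at the top of the canopy.
traits:
  lma: 138.0
  leaf_n: 0.0215
  f_cleaf: 0.2
  f_s: 0.54
  d_ns: 50.4
environment:
  par: 621.0
  co2_ppm: 370.0
  day_temp: 17.0
  night_temp: 13.0
  rh: 0.6
  day_hours: 17.0
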