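# Generic evergreen tree trait set with the sensitivity-analysis control
# environment.
traits:
  lma: 85.0
  leaf_n: 0.015
  f_s: 0.5
  d_ns: 50.0
  f_cleaf: 0.2
environment:
  par: 800.0
  co2_ppm: 370.0
  day_temp: 15.0
  night_temp: 15.0
  rh: 0.8
  day_hours: 14.0
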