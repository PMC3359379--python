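# Test case 2 treatment arm at relative light x = 0.5: PAR = 621 * x and
# LMA from the canopy light regression 73 + 65.5 * x.
traits:
  lma: 105.75
  leaf_n: 0.0215
  f_cleaf: 0.2
  f_s: 0.54
  d_ns: 50.4
environment:
  par: 310.5
  co2_ppm: 370.0
  day_temp: 17.0
  night_temp: 13.0
  rh: 0.6
  day_hours: 17.0
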