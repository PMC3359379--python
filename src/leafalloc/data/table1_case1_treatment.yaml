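# Test case 1 treatment arm: elevated CO2 (570 ppm); all else as control.
traits:
  lma: 85.0
  leaf_n: 0.014
  f_cleaf: 0.2
  f_s: 0.86
  d_ns: 85.2
environment:
  par: 1010.0
  co2_ppm: 570.0
  day_temp: 28.0
  night_temp: 23.0
  rh: 0.8
  day_hours: 14.0
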