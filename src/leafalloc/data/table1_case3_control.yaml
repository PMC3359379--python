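# Test case 3 control arm: plantain grown at 30 C.
traits:
  lma: 55.0
  leaf_n: 0.03
  f_cleaf: 0.6
  f_s: 0.52
  d_ns: 3.98
environment:
  par: 450.0
  co2_ppm: 370.0
  day_temp: 30.0
  night_temp: 30.0
  rh: 0.8
  day_hours: 14.0
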