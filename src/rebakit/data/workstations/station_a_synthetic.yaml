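name: station_a_synthetic
surface_height_mm: 1222.6356117411335
work_point:
  horizontal_offset_mm: 429.10885061964365
  height_mm: 1222.6356117411335
adjustable:
- surface_height
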