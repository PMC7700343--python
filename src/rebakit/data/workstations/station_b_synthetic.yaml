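name: station_b_synthetic
surface_height_mm: 1190.9966707836857
work_point:
  horizontal_offset_mm: 418.0936014129161
  height_mm: 1412.318881625968
adjustable:
- tool_height
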