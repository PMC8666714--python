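# Reference 150 mL perfusion run (all values shown are the defaults;
# any section may be omitted). Units are embedded in the key names.
parameters:
  K_Lac: 50.0            # mM
  mu_max: 1.35           # 1/day
media:
  feed_i:
    glc_mM: 34.15
    gln_mM: 4.5
    lac_mM: 0.0
    osm_mOsm_kg: 337.5
  feed_ii:
    glc_mM: 42.48
    gln_mM: 5.0
    lac_mM: 0.0
    osm_mOsm_kg: 352.5
schedule:
  - {start_day: 0, end_day: 1, rate_vvd: 0}
  - {start_day: 1, end_day: 2, rate_vvd: 1,   medium: feed_i}
  - {start_day: 2, end_day: 3, rate_vvd: 1.5, medium: feed_i}
  - {start_day: 3, end_day: 4, rate_vvd: 3,   medium: feed_i}
  - {start_day: 4, end_day: 5, rate_vvd: 4,   medium: feed_ii}
  - {start_day: 5, end_day: 6, rate_vvd: 6,   medium: feed_ii}
  - {start_day: 6, end_day: 7, rate_vvd: 7,   medium: feed_ii}
initial_state:
  X_cells_per_mL: 0.5e6
  volume_L: 0.15
  glc_mM: 17.5
  gln_mM: 2.5
  lac_mM: 0.0
  osm_mOsm_kg: 317.5
integration:
  dt_out: 0.05
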