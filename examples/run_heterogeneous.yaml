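baseline:
  a260:
  - - 7.85
    - 0.1925
  - - 9.35
    - 0.2675
  a280:
  - - 7.85
    - 0.1925
  - - 9.35
    - 0.2675
genome:
  n_nt: 4787
mp:
  full_mass_kda: 5213.8909
peak_window:
  v_end_ml: 9.35
  v_start_ml: 7.85
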