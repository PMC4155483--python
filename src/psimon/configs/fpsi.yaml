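# Freshly etched porous-Si rugate film monitored in flowing pH-10 buffer.
# Stop band placed at 593 nm; pore-wall dissolution tuned to an initial
# rugate blue shift of 1.33 nm/min.
name: fpSi
seed: 0
sample:
  porosity: 0.534
  thickness_um: 22.8
  rugate_amplitude: 0.015
  rugate_peak_nm: 593.0
  skeleton: Si
  pore_fill: buffer
  ambient: buffer
  substrate: Si
degradation:
  rugate_shift_nm_per_min: 1.33
  t_end_min: 300.0
  t_step_min: 5.0
camera:
  illuminant_k: 3000.0
  white_balance: none
analysis:
  search_band: [430.0, 750.0]
  fft_band: [650.0, 1000.0]
  rate_window: [0.0, 25.0]
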