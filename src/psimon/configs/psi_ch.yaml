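# Chitosan-capped porous-Si rugate film (pSi-ch): same film as fpSi plus a
# 5.6-um chitosan overlayer; degrades faster (1.99 nm/min initial shift).
name: pSi-ch
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
  overlayer:
    medium: chitosan
    thickness_um: 5.6
degradation:
  rugate_shift_nm_per_min: 1.99
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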