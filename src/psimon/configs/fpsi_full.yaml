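# Complete-degradation scenario: pore walls dissolve entirely by 100 min
# (porosity -> 1), after which the camera sees the bare Si substrate under
# the tungsten-like 3000 K illuminant. Used to contrast raw hue (rises then
# falls once the lamp reflection off bare Si dominates) with the
# monotonically increasing H parameter.
name: fpSi-full
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
  porosity_rate: 0.00466   # (1 - 0.534) / 100 min
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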