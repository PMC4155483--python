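# psimon

Optical and colorimetric monitoring of porous-silicon photonic-crystal
degradation.

Porous silicon (pSi) films etched with a periodic current waveform are
one-dimensional photonic crystals (rugate filters): a sinusoidal porosity
depth profile produces a narrow reflectance stop band whose position and
the film's Fabry–Pérot fringe pattern both report on the film's state. As
the film degrades in aqueous media — pore walls oxidize and dissolve — the
stop band shifts to the blue (hypsochromic shift) and the effective optical
thickness EOT = 2nL decays. These are the standard spectrophotometric
degradation monitors for self-reporting drug-delivery carriers. The same
degradation is visible to a consumer camera as a red-to-green color change,
which makes low-cost, spectrometer-free monitoring possible if a robust
single color parameter can be extracted from the image time series.

`psimon` implements both monitoring paths and the forward models needed to
test them without laboratory data:

- **Forward optics** — transfer-matrix reflectance of rugate film stacks
  (optional polymer cap, degrading porous layer, Si substrate), with the
  two-component Bruggeman effective-medium rule
  `(1−p)(ε_sk−ε)/(ε_sk+2ε) + p(ε_f−ε)/(ε_f+2ε) = 0` linking porosity to
  refractive index, a linear-in-time degradation model (thickness loss,
  pore-wall dissolution, Si→SiO₂ oxidation), and the SLIM inversion that
  recovers (porosity, thickness) from EOT measured with two pore-filling
  media.
- **Spectral analysis** — rugate-peak tracking with sub-grid refinement,
  EOT extraction by FFT of the interference fringes on a uniform 1/λ grid
  (the RIFTS procedure), layer decomposition via EOT₁ + EOT₂ = EOT₃,
  relative EOT change ΔEOT/EOT₀ × 100%, and least-squares initial-rate
  fits.
- **Color pipeline** — spectrum-to-RGB rendering through a colorimeter
  model (Gaussian channel sensitivities, Planck 3000 K tungsten-like
  illuminant, white balance, sRGB encoding), HSV hue on the 0–1 scale, and
  the *H* parameter: hue recomputed after each channel is independently
  min–max normalized over the time course, plus the normalized curve
  (H − H_init)/(H_max − H_init) used to compare samples.
- **Imaging I/O** — synthetic time-lapse image stacks (ROI disc, reference
  patch, manifest) and mean-ROI RGB extraction with reference-patch
  balancing.
- **CLI** — `psimon simulate / extract / analyze / report`, all driven by
  one YAML config.

## Worked example

Simulate the two bundled samples — a freshly etched film (`fpsi`, initial
rugate shift 1.33 nm/min) and a chitosan-capped film (`psi_ch`,
1.99 nm/min) — then analyze and rank them:

```sh
CFG=$(python -c "import psimon,os;print(os.path.dirname(psimon.__file__)+'/configs')")
psimon simulate -c $CFG/fpsi.yaml   -o fpsi   --seed 1
psimon simulate -c $CFG/psi_ch.yaml -o psi_ch --seed 1
psimon analyze  -c $CFG/fpsi.yaml   -s fpsi/spectra   --rgb fpsi/rgb_series.csv   -o fpsi/analysis
psimon analyze  -c $CFG/psi_ch.yaml -s psi_ch/spectra --rgb psi_ch/rgb_series.csv -o psi_ch/analysis
psimon report fpSi=fpsi/analysis pSi-ch=psi_ch/analysis --window 0 25
```

prints

```
Stability report (initial-rate window 0-25 min)

        rel_eot_pct_per_min  rugate_nm_per_min  h_norm_per_min
fpSi               -0.22569            -1.2963        0.009973
pSi-ch             -0.33617             -1.924        0.013527

rel_eot_pct_per_min: most stable -> least stable: fpSi > pSi-ch
rugate_nm_per_min: most stable -> least stable: fpSi > pSi-ch
h_norm_per_min: most stable -> least stable: fpSi > pSi-ch

metrics agree: True
```

Reading the table: the fpSi film loses relative optical thickness at
0.23 %/min and its stop band shifts at 1.30 nm/min over the first 25 min
(within a few percent of the 1.33 nm/min the simulation was built to
produce), while the capped film degrades ~1.5× faster; the camera-side
H-parameter rate ranks the samples identically, so a consumer camera
reproduces the spectrometer's stability ordering, fpSi > pSi-ch.

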