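# Methods

## Optical forward model

The film stack is modeled at normal incidence with the characteristic
(transfer) matrix method using real refractive indices; absorption,
oblique incidence, polarization and pore-scale scattering are neglected.
Media follow a two-term Cauchy law n(λ) = A + B/λ² (λ in nm). Defaults,
all configuration rather than code: Si A = 3.42, B = 2×10⁴ nm² (mild
normal dispersion in the visible), SiO₂ 1.46, ethanol 1.36, aqueous
buffer 1.35, chitosan 1.54, air 1.0.

A porous layer's effective index comes from the two-component Bruggeman
effective-medium rule. Clearing denominators turns the self-consistency
condition into a quadratic in ε = n² whose unique positive root is the
physical branch (it reduces to each pure component at p = 0, 1 and lies
between them); the closed form is used everywhere and is verified against
a brute-force sign-scan of the residual in the tests.

Rugate layers have porosity profile p(z) = p̄ + a·sin(2πz/Λ) and are
discretized at 20 sublayers per period; halving the step (40 per period)
changes reflectance by < 0.5 %, which is the convergence criterion used.
Because every full period has the same characteristic matrix (per
wavelength), the periodic section is evaluated by binary exponentiation of
the unit-period matrix — algebraically identical to the plain product —
with any partial final period multiplied in sublayer by sublayer. The
stop band falls at the first-order Bragg condition λ = 2·n_eff(p̄)·Λ,
which the peak-placement test checks to within two grid steps.

Degradation is linear in time per mechanism, each clipped to its physical
range: thickness L(t) = max(0, L₀ − k_L·t); mean porosity
p(t) = min(1, p₀ + k_p·t) (pore-wall dissolution); skeleton dielectric
blended Si → SiO₂ by the oxidized fraction min(1, k_ox·t). This is the
simplest model reproducing the observed monotone blue shift and EOT loss.
The rugate amplitude is clipped so p ± a stays in [0, 1]; once a layer's
thickness (or solid fraction) reaches zero the spectrum tends to the bare
substrate Fresnel response. The working grid is 400–1000 nm at 0.5 nm
(the spectrometer range); optional reflectance noise is additive Gaussian,
seeded, default off.

SLIM (spectroscopic liquid infiltration) inverts the pair
EOT_air = 2·n_eff(p; air)·L, EOT_fill = 2·n_eff(p; fill)·L by a bracketed
1-D root search in p on (0, 1) (Brent, xtol 10⁻¹⁵), then reads off L.
Identical media, non-positive EOTs, or an infiltration that fails to raise
the EOT raise an inconsistent-measurements error. Round trips recover
(p, L) to 10⁻⁶ relative.

## Spectral analysis

EOT extraction follows the standard reflectometric-interference recipe:
restrict to the configured fringe band, resample reflectance onto a
uniform 1/λ grid by linear interpolation, remove the best-fit line (mean
plus linear baseline, suppressing the zero-frequency lobe), apply a Hann
window, zero-pad to ≥ 2¹⁶ points and take the magnitude FFT. In these
units the frequency axis is the EOT axis directly. The n largest local
maxima above 3× the median magnitude are reported with parabolic sub-bin
refinement; peaks below 2 µm are treated as baseline residue. The
resolution quoted is λ_min·λ_max/(2(λ_max−λ_min)) — about 0.33 µm on the
full grid. Ties in amplitude order the smaller EOT first.

The fringe band defaults to 650–1000 nm for film analysis: the moving stop
band interrupts the fringe phase and, if included, splits the affected FFT
components (the laboratory procedure likewise transformed only the portion
of the spectrum showing clean fringes). For a capped film the two dominant
FFT components are the porous layer alone and the full stack; their
difference is the overlayer's own 2nL (EOT₁ + EOT₂ = EOT₃). Note the FFT
measures a *group* optical thickness: with dispersive media it sits
slightly above 2nL evaluated at a single wavelength, which is why
layer-decomposition checks compare against the difference of components
rather than phase values.

Series analysis tracks the dominant t = 0 EOT peak by nearest-neighbour
continuity. A frame whose candidate amplitude falls below 2 % of the
initially tracked amplitude is flagged missing: in the forward model the
residual curvature of a bare-substrate spectrum produces FFT peaks roughly
10⁴× weaker than genuine film fringes, so this floor cleanly separates
"film gone" from "film present" (the 3×-median noise floor alone cannot,
because zero-padding drives the median magnitude toward zero). Rugate
peaks are refined parabolically; a maximum on the search-band edge is
flagged and treated as missing. Missing values propagate as NaN and are
excluded from rate fits, never aborting a series.

Initial rates are ordinary least-squares slopes over a configurable
window, default the first 25 min (degradation rates change after the early
phase); at least 3 finite points are required. Stability ranking uses
|slope|; whether the laboratory fits used least squares was not specified,
and OLS is the conventional choice.

## Camera model and hue monitors

The camera is a fixed-settings colorimeter: Gaussian channel
sensitivities centered 600/540/465 nm with 80 nm FWHM, a Planck blackbody
illuminant at 3000 K (tungsten-like), per-channel white-balance gains,
exposure 0.9 (a 100 % reflector renders just below clipping) and sRGB
encoding. Channel c integrates gain_c·exposure·∫S_c·I·R dλ
(trapezoidal). Two balance policies exist: `neutral` computes gains that
render a flat reflector gray under the camera's own illuminant; `none`
applies a single common scale, leaving the illuminant's red-rich cast in
place — this is the default for degradation scenarios because the
experimental observation being modeled (hue falling once the bare wafer's
lamp reflection dominates) only exists when the cast survives. Hue is
computed on the gamma-encoded 8-bit-scale values, matching as-acquired
camera files; a linear-gamma mode is available.

Hue is standard hexagonal HSV hue divided to the 0–1 scale; achromatic
triplets (max = min) return NaN rather than 0, since the angle is
undefined. The H parameter recomputes hue after each channel has been
min–max normalized independently over the whole time course (rescaled to
0–255); a constant channel maps to mid-scale 127.5, keeping it defined
but non-informative. The normalization is retrospective by construction —
it needs the whole series — so streaming use is out of scope. The
normalized curve h_norm = (H − H_init)/(H_max − H_init) anchors at 0 and
reaches 1 at the series maximum.

Simulated RGB series carry float channel means rather than quantized
integers: the laboratory quantity is a mean over ~10⁵ ROI pixels, which
resolves far below one 8-bit count. Per-pixel quantization is applied
where it belongs, when fixture images are written; the round trip through
images recovers means to ±0.5 count (noiseless) or to the CLT bound
(noisy).

## Study scenarios and what the synthetic data does not show

Bundled configurations define the study conditions. The film is the
characterized freshly etched sample: porosity 53.4 %, thickness 22.8 µm,
stop band at 593 nm (the rugate period is derived from the Bragg
condition under the buffer-filled pore state), modulation amplitude 0.015
— chosen to give a ~14 nm stop-band width, inside the 10–30 nm range
typical of these films, and an unsaturated peak. Monitoring runs 300 min
at 5-min cadence.

- `fpsi.yaml` / `psi_ch.yaml`: pore-wall dissolution rates calibrated (by
  linearizing the Bragg condition in porosity) to initial stop-band shifts
  of 1.33 and 1.99 nm/min, the slower/faster pair used for stability
  ranking; the capped sample adds a 5.6 µm chitosan overlayer.
- `fpsi_full.yaml`: complete degradation by pore-wall dissolution alone,
  porosity reaching 1 at 100 min, after which the frames show the bare
  wafer under the tungsten-like lamp. This mechanism choice (rather than
  top-down thinning) follows the experimental inference that the films
  degraded by pore-wall dissolution, and it lets the stop band fade
  smoothly into the substrate response instead of passing through
  sub-micron thin-film interference colors that a laterally averaged
  laboratory image would not show.

The "pre-dissolution window" used for the hue/wavelength correlation is
defined operationally: frames with a measurable in-band rugate peak
(above 440 nm, before the first dropout). Beyond it the in-band maximum
is fringe ripple, not the stop band.

The generator emulates: narrow-band rugate reflectance with Fabry–Pérot
fringes, monotone blue shift and EOT loss, the post-dissolution
bare-substrate state, tungsten-lit 8-bit frames with ROI/reference
geometry, and seeded noise. It does not emulate: lateral inhomogeneity of
degradation, bubbles or flow artifacts, illumination drift, camera
demosaicing/JPEG artifacts (a JPEG fixture mode exists but is not the
default), absorption in Si at short wavelengths, or calibrated
CIE colorimetry. Passing tests therefore demonstrate the correctness and
internal consistency of the algorithms under the stated model, not
quantitative agreement with any particular laboratory sample; laboratory
rate values and hue endpoints depend on the samples themselves and are
used here only as simulation inputs or qualitative patterns.

## Numerical choices and edge cases

- Bruggeman: closed-form positive quadratic root; out-of-bracket roots
  raise an arithmetic error.
- Transfer matrix: complex 2×2 matrices vectorized over wavelength;
  zero-thickness layers contribute the identity.
- Peak refinement: three-point parabola, shift clipped to ±1 bin/step.
- H-parameter monotonicity is a circular statement; where a series
  legitimately crosses the hue origin the tests compare shortest-arc
  increments. The canonical complete-degradation scenario stays within
  one revolution and is monotone without unwrapping.
- Degenerate inputs: flat spectra raise a no-peak error; single-frame
  series cannot be normalized; identical SLIM media are rejected;
  constant series fit slope exactly 0 with r² = 1 by convention.
- Problem sizes: the default 0.5 nm grid (1201 points), 61-frame series
  and 14-configuration property sweeps keep the full suite and the
  acceptance script in the tens-of-seconds range on one CPU.

## Known limitations

Real-valued indices understate reflectance below ~500 nm where crystalline
Si absorbs; the EOT reported is a group quantity (no dispersion
correction is applied); the degradation laws are phenomenological and
linear; the camera model is not a calibrated replica of any specific
sensor, and the reference-patch balance is an equivalent of, not a replica
of, interactive curve tools used on laboratory images.
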