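"""Camera rendering and hue-based degradation monitors.

The simulation path of the imaging experiment: a reflectance spectrum is
rendered to an 8-bit RGB triplet through a simple colorimeter model
(Gaussian channel sensitivities, Planck blackbody illuminant, white-balance
gains, exposure, gamma encoding). From an RGB time series the module
computes

* the raw HSV hue per frame (dominant-color angle, reported on a 0-1
  scale, undefined for achromatic frames);
* the H parameter: hue recomputed after each channel has been min-max
  normalized independently over the whole time course, which removes the
  broad illuminant reflection that makes raw hue non-monotonic late in the
  degradation; and
* the normalized H curve (H - H_initial)/(H_max - H_initial) used to
  compare samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.constants import c, h, k

from .optics import ReflectanceSpectrum
from .spectral import RateFit, fit_rate

__all__ = [
    "CameraModel",
    "RGBSeries",
    "HueSeries",
    "planck_spectrum",
    "render_rgb",
    "reference_balance",
    "compute_hue",
    "minmax_normalize_channels",
    "compute_h_parameter",
    "color_rate",
]


def planck_spectrum(wavelength_nm, temperature_k: float) -> np.ndarray:
    """Relative blackbody spectral power at ``temperature_k`` (peak = 1)."""
    lam = np.asarray(wavelength_nm, dtype=float) * 1e-9
    power = lam**-5 / np.expm1(h * c / (lam * k * temperature_k))
    return power / power.max()


def _gaussian(lam, center, fwhm):
    sigma = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    return np.exp(-0.5 * ((lam - center) / sigma) ** 2)


def srgb_encode(linear):
    """sRGB opto-electronic transfer function on [0, 1] values."""
    v = np.asarray(linear, dtype=float)
    return np.where(v <= 0.0031308, 12.92 * v,
                    1.055 * np.clip(v, 0.0, None) ** (1 / 2.4) - 0.055)


@dataclass(frozen=True)
class CameraModel:
    """Colorimeter model of a fixed-settings consumer camera.

    Channel sensitivities are Gaussians at ``channel_centers`` (nm) with a
    common ``channel_fwhm`` (nm); the scene illuminant is a Planck
    blackbody at ``illuminant_k`` (the tungsten source is ~3000 K).
    ``white_balance_gains`` multiply the raw channel integrals; the
    ``neutral`` policy computes them so a 100% flat reflector renders
    neutral under this camera's own illuminant (ideal in-scene balance),
    while ``none`` leaves the illuminant cast in place (gains all 1,
    exposure rescaled to avoid clipping), reproducing the red-rich tungsten
    rendering of a camera whose preset balance does not cancel the lamp.
    ``gamma`` is "srgb", a numeric encoding exponent, or 1.0 for linear.
    """

    channel_centers: tuple = (600.0, 540.0, 465.0)
    channel_fwhm: float = 80.0
    illuminant_k: float = 3000.0
    white_balance: str = "neutral"     # "neutral" | "none"
    exposure: float = 0.9
    gamma: object = "srgb"
    wavelengths: np.ndarray = field(
        default_factory=lambda: np.arange(400.0, 1000.5, 0.5))

    def sensitivities(self, lam) -> np.ndarray:
        """(3, n) channel response curves on grid ``lam``."""
        lam = np.asarray(lam, dtype=float)
        return np.stack([_gaussian(lam, cc, self.channel_fwhm)
                         for cc in self.channel_centers])

    def illuminant(self, lam) -> np.ndarray:
        return planck_spectrum(lam, self.illuminant_k)

    def _raw_white(self, lam) -> np.ndarray:
        """Per-channel integral for a 100% flat reflector (no gains)."""
        resp = self.sensitivities(lam) * self.illuminant(lam)
        return np.trapezoid(resp, lam, axis=1)

    def gains(self, lam) -> np.ndarray:
        white = self._raw_white(lam)
        if np.any(white <= 0):
            raise ValueError("camera has a dead channel on this grid")
        if self.white_balance == "neutral":
            return 1.0 / white
        if self.white_balance == "none":
            # common scale only: flat reflector's brightest channel -> 1
            return np.full(3, 1.0 / white.max())
        raise ValueError(f"unknown white_balance {self.white_balance!r}")

    def encode(self, linear):
        if self.gamma == "srgb":
            return srgb_encode(linear)
        g = float(self.gamma)
        return np.clip(np.asarray(linear, dtype=float), 0.0, None) ** (1.0 / g)


def render_rgb(spec: ReflectanceSpectrum, camera: CameraModel | None = None,
               quantize: bool = True) -> np.ndarray:
    """Render a reflectance spectrum to an RGB triplet on the 0-255 scale.

    Each channel is gain * exposure * integral of S_c(lambda) * I(lambda) *
    R(lambda) d lambda (trapezoidal), gamma-encoded and clipped to [0, 255];
    with ``quantize`` the triplet is rounded to integers (8-bit camera
    output), otherwise returned as floats (useful for algebraic checks
    ahead of quantization). Deterministic.
    """
    camera = camera or CameraModel()
    lam = camera.wavelengths
    refl = np.interp(lam, spec.wavelengths, spec.reflectance)
    resp = camera.sensitivities(lam) * camera.illuminant(lam) * refl
    raw = np.trapezoid(resp, lam, axis=1)
    linear = camera.gains(lam) * camera.exposure * raw
    rgb = np.clip(camera.encode(linear) * 255.0, 0.0, 255.0)
    if quantize:
        rgb = np.round(rgb)
    return rgb


def reference_balance(rgb, reference_rgb):
    """Per-channel rescaling that maps a reference patch to neutral gray.

    Divides each channel by the reference value and multiplies by the
    reference luminance mean, so the reference patch becomes gray at its
    own brightness; results are clipped to [0, 255]. Scale-invariant:
    balance(k*rgb, k*ref) = balance(rgb, ref) before clipping.
    """
    rgb = np.asarray(rgb, dtype=float)
    ref = np.asarray(reference_rgb, dtype=float)
    if np.any(ref <= 0):
        raise ValueError("reference channels must all be > 0")
    return np.clip(rgb * (ref.mean() / ref), 0.0, 255.0)


def compute_hue(rgb) -> float:
    """HSV hue of an RGB triplet on the 0-1 scale; NaN if achromatic.

    Standard hexagonal hue: with M = max(R,G,B), m = min(R,G,B) and
    C = M - m, h' = (G-B)/C (M=R), (B-R)/C + 2 (M=G), (R-G)/C + 4 (M=B);
    the angle h'/6 is wrapped into [0, 1). M = m has no dominant color and
    returns NaN.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape != (3,):
        raise ValueError("rgb must be a triplet")
    if np.any(rgb < 0) or np.any(rgb > 255):
        raise ValueError("channels must lie in [0, 255]")
    r, g, b = rgb
    mx = rgb.max()
    mn = rgb.min()
    chroma = mx - mn
    if chroma == 0:
        return float("nan")
    if mx == r:
        hp = (g - b) / chroma
    elif mx == g:
        hp = (b - r) / chroma + 2.0
    else:
        hp = (r - g) / chroma + 4.0
    hue = hp / 6.0
    if hue < 0:
        hue += 1.0
    return float(hue)


@dataclass
class RGBSeries:
    """Mean ROI RGB per frame; channels on the 0-255 scale."""

    times: np.ndarray
    rgb: np.ndarray  # (n, 3)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.rgb, dtype=float)
        if v.ndim != 2 or v.shape != (t.size, 3):
            raise ValueError("rgb must have shape (n_times, 3)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(v < 0) or np.any(v > 255):
            raise ValueError("channels must lie in [0, 255]")
        self.times = t
        self.rgb = v

    def __len__(self):
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_min": self.times, "R": self.rgb[:, 0],
                             "G": self.rgb[:, 1], "B": self.rgb[:, 2]})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RGBSeries":
        return cls(df["time_min"].to_numpy(float),
                   df[["R", "G", "B"]].to_numpy(float))


@dataclass
class HueSeries:
    """Hue-based monitors per frame (NaN where undefined)."""

    times: np.ndarray
    hue: np.ndarray       # raw HSV hue of the as-acquired means
    h_param: np.ndarray   # hue of the min-max normalized channels
    h_norm: np.ndarray    # (H - H_initial) / (H_max - H_initial)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_min": self.times, "hue": self.hue,
                             "h_param": self.h_param, "h_norm": self.h_norm})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HueSeries":
        return cls(df["time_min"].to_numpy(float), df["hue"].to_numpy(float),
                   df["h_param"].to_numpy(float),
                   df["h_norm"].to_numpy(float))


def minmax_normalize_channels(series: RGBSeries) -> RGBSeries:
    """Independently min-max normalize each channel over the time course.

    Each channel is mapped by (x - min)/(max - min) onto [0, 1] using its
    own extrema over the whole series, then rescaled to the 0-255 range so
    hue can be recomputed on the processed values. A constant
    (non-informative) channel maps to mid-scale 127.5 everywhere. Affine-
    invariant: normalize(a*x + b) = normalize(x) for a > 0.
    """
    if len(series) < 2:
        raise ValueError("normalization needs at least 2 frames")
    v = series.rgb
    lo = v.min(axis=0)
    hi = v.max(axis=0)
    out = np.empty_like(v)
    for ch in range(3):
        if hi[ch] == lo[ch]:
            out[:, ch] = 127.5
        else:
            out[:, ch] = (v[:, ch] - lo[ch]) / (hi[ch] - lo[ch]) * 255.0
    return RGBSeries(series.times.copy(), out)


def compute_h_parameter(series: RGBSeries) -> HueSeries:
    """Raw hue, H parameter and normalized H for an RGB time series.

    ``hue`` is computed frame-by-frame from the as-acquired channel means;
    ``h_param`` from the min-max normalized channels; ``h_norm`` rescales
    the H-parameter curve by its initial and maximum values, so it starts
    at 0 and reaches 1 at the series maximum. Normalization is
    retrospective: it uses extrema over the whole series.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 frames")
    hue = np.array([compute_hue(x) for x in series.rgb])
    normed = minmax_normalize_channels(series)
    h_param = np.array([compute_hue(x) for x in normed.rgb])
    if np.all(np.isnan(h_param)):
        warnings.warn("all frames achromatic; hue undefined throughout",
                      UserWarning, stacklevel=2)
        h_norm = np.full(len(series), np.nan)
    else:
        finite = h_param[np.isfinite(h_param)]
        h_init = finite[0]
        h_max = finite.max()
        if h_max == h_init:
            h_norm = np.where(np.isfinite(h_param), 0.0, np.nan)
        else:
            h_norm = (h_param - h_init) / (h_max - h_init)
    return HueSeries(series.times.copy(), hue, h_param, h_norm)


def color_rate(series: HueSeries, window: tuple | None = None) -> RateFit:
    """OLS initial rate of the normalized H curve (units 1/min)."""
    return fit_rate(series.times, series.h_norm, window)
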