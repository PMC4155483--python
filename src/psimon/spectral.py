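"""Degradation signals from reflectance spectra.

Two spectroscopic observables track porous-silicon degradation:

* the wavelength of the rugate stop-band maximum, which blue-shifts as the
  pore walls dissolve and oxidize (hypsochromic shift); and
* the effective optical thickness EOT = 2nL, read out as the frequency of
  the Fabry-Perot interference fringes when the reflectance is expressed
  against wavenumber 1/lambda (the RIFTS procedure: resample to a uniform
  1/lambda grid, detrend, window, zero-padded FFT, pick peaks).

For a polymer-capped film the FFT shows one peak per interface pair; the
two dominant peaks (porous layer alone, full stack) differ by the
overlayer's own 2nL, EOT1 + EOT2 = EOT3.

Degradation is summarized by the relative EOT change
(EOT(t) - EOT(0))/EOT(0) x 100% and by least-squares initial rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import find_peaks

from .optics import ReflectanceSpectrum

__all__ = [
    "EOTResult",
    "DegradationSeries",
    "RateFit",
    "NoPeakError",
    "EdgePeakWarning",
    "find_rugate_peak",
    "compute_eot",
    "relative_eot_change",
    "decompose_layers",
    "fit_rate",
    "analyze_series",
    "write_series_csv",
    "read_series_csv",
]

FFT_PAD = 1 << 16  # zero-padding length floor for the fringe FFT


class NoPeakError(ValueError):
    """Spectrum has no usable maximum in the requested band."""


class EdgePeakWarning(UserWarning):
    """Band maximum sits on the search-band edge; position unreliable."""


@dataclass(frozen=True)
class EOTResult:
    """FFT fringe-analysis result.

    ``peak_positions`` are EOT values (2nL) in um, ordered by descending
    fringe amplitude; ``resolution`` is the physical EOT spacing resolvable
    from the spectral span, lambda_min*lambda_max/(2*(lambda_max-lambda_min)).
    """

    peak_positions: np.ndarray
    peak_amplitudes: np.ndarray
    resolution: float

    def __post_init__(self):
        pos = np.atleast_1d(np.asarray(self.peak_positions, dtype=float))
        amp = np.atleast_1d(np.asarray(self.peak_amplitudes, dtype=float))
        if pos.size != amp.size:
            raise ValueError("positions and amplitudes must have equal length")
        if np.any(pos <= 0) or np.any(amp < 0):
            raise ValueError("positions must be > 0 and amplitudes >= 0")
        object.__setattr__(self, "peak_positions", pos)
        object.__setattr__(self, "peak_amplitudes", amp)

    @property
    def n_peaks(self) -> int:
        return self.peak_positions.size


@dataclass(frozen=True)
class RateFit:
    """Ordinary-least-squares slope over a time window."""

    slope: float
    intercept: float
    window: tuple
    r_squared: float
    n_points: int = 0


@dataclass
class DegradationSeries:
    """Per-time rugate peak, tracked EOT and relative EOT change (%).

    Missing frames (no detectable peak, e.g. after complete dissolution)
    are carried as NaN, never dropped.
    """

    times: np.ndarray
    rugate_peak: np.ndarray
    eot: np.ndarray
    rel_eot_change: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_min": self.times,
            "rugate_peak_nm": self.rugate_peak,
            "eot_um": self.eot,
            "rel_eot_pct": self.rel_eot_change,
        })


def find_rugate_peak(spec: ReflectanceSpectrum,
                     search_band: tuple = (450.0, 750.0)) -> float:
    """Wavelength (nm) of the reflectance maximum within ``search_band``.

    The grid maximum is refined by three-point parabolic interpolation for
    sub-grid precision. A maximum on the band edge triggers
    ``EdgePeakWarning`` (the true peak may lie outside the band); a flat
    spectrum raises ``NoPeakError``.
    """
    lam = spec.wavelengths
    lo, hi = search_band
    sel = (lam >= lo) & (lam <= hi)
    if sel.sum() < 3:
        raise NoPeakError("search band contains fewer than 3 grid points")
    lam_b = lam[sel]
    r_b = spec.reflectance[sel]
    if np.ptp(r_b) < 1e-12:
        raise NoPeakError("spectrum is flat within the search band")
    i = int(np.argmax(r_b))
    if i == 0 or i == r_b.size - 1:
        warnings.warn("band maximum lies on the search-band edge",
                      EdgePeakWarning, stacklevel=2)
        return float(lam_b[i])
    y0, y1, y2 = r_b[i - 1], r_b[i], r_b[i + 1]
    denom = y0 - 2 * y1 + y2
    shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    shift = float(np.clip(shift, -1.0, 1.0))
    # local grid may be non-uniform; use the mean neighbour spacing
    step = 0.5 * (lam_b[i + 1] - lam_b[i - 1])
    return float(lam_b[i] + shift * step)


def _parabolic(mag, i):
    y0, y1, y2 = mag[i - 1], mag[i], mag[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return 0.0
    return float(np.clip(0.5 * (y0 - y2) / denom, -1.0, 1.0))


def compute_eot(spec: ReflectanceSpectrum, n_peaks: int = 1,
                band: tuple | None = None, min_eot_um: float = 2.0) -> EOTResult:
    """EOT peaks from the Fabry-Perot fringes of a reflectance spectrum.

    Pipeline: restrict to ``band`` (nm) if given; resample onto a uniform
    1/lambda grid (linear interpolation); remove the best-fit line (mean +
    linear baseline) to suppress the zero-frequency lobe; Hann window;
    zero-pad to >= 2**16 points; magnitude FFT. In these units the FFT
    frequency axis (cycles per nm^-1) *is* the EOT axis in nm. The
    ``n_peaks`` largest local maxima above a noise floor of 3x the median
    magnitude are returned with parabolic sub-bin refinement; peaks below
    ``min_eot_um`` are treated as baseline residue and ignored. Fewer
    detectable peaks than requested yields a shorter result with a warning.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    lam = spec.wavelengths
    refl = spec.reflectance
    if band is not None:
        sel = (lam >= band[0]) & (lam <= band[1])
        lam, refl = lam[sel], refl[sel]
    if lam.size < 8 or lam[-1] - lam[0] < 100.0:
        raise ValueError("spectrum must span at least 100 nm")

    k = 1.0 / lam[::-1]          # wavenumber grid, increasing
    r_k = refl[::-1]
    ku = np.linspace(k[0], k[-1], lam.size)
    r_u = np.interp(ku, k, r_k)
    coef = np.polyfit(ku, r_u, 1)
    r_d = (r_u - np.polyval(coef, ku)) * np.hanning(lam.size)

    n_fft = FFT_PAD
    while n_fft < 4 * lam.size:
        n_fft *= 2
    mag = np.abs(np.fft.rfft(r_d, n_fft))
    freq_nm = np.fft.rfftfreq(n_fft, ku[1] - ku[0])  # EOT axis in nm

    resolution_um = (lam[0] * lam[-1] / (2.0 * (lam[-1] - lam[0]))) * 1e-3
    floor = 3.0 * np.median(mag)
    usable = freq_nm >= min_eot_um * 1e3
    idx_all, _ = find_peaks(mag)
    idx = idx_all[(mag[idx_all] > floor) & usable[idx_all]]
    if idx.size < n_peaks:
        warnings.warn(
            f"only {idx.size} EOT peak(s) above the noise floor "
            f"({n_peaks} requested)", UserWarning, stacklevel=2)
    order = np.argsort(mag[idx])[::-1][:n_peaks]
    chosen = idx[order]
    positions = []
    amplitudes = []
    for i in chosen:
        shift = _parabolic(mag, i)
        positions.append((freq_nm[i] + shift * (freq_nm[1] - freq_nm[0])) * 1e-3)
        amplitudes.append(float(mag[i]))
    positions = np.array(positions)
    amplitudes = np.array(amplitudes)
    # descending amplitude; equal amplitudes -> smaller EOT first
    order = np.lexsort((positions, -amplitudes))
    return EOTResult(positions[order], amplitudes[order], resolution_um)


def relative_eot_change(eot_t: float, eot_0: float) -> float:
    """Relative EOT change (EOT(t) - EOT(0)) / EOT(0) x 100, in percent."""
    if eot_0 <= 0:
        raise ValueError("eot_0 must be > 0")
    return (eot_t - eot_0) / eot_0 * 100.0


def decompose_layers(eot: EOTResult) -> dict:
    """Assign the two dominant FFT peaks to the film layers.

    The smaller EOT belongs to the porous-Si layer alone, the larger to the
    full stack (overlayer top surface to substrate); their difference is
    the overlayer's own 2nL. Returns a dict with keys ``pSi``,
    ``full_stack`` and ``overlayer`` (um).
    """
    if eot.n_peaks < 2:
        raise ValueError("layer decomposition needs at least 2 EOT peaks")
    two = eot.peak_positions[:2]
    psi, full = float(two.min()), float(two.max())
    return {"pSi": psi, "full_stack": full, "overlayer": full - psi}


def fit_rate(times, values, window: tuple | None = None) -> RateFit:
    """OLS slope of ``values`` against ``times`` (min) inside ``window``.

    NaN values are excluded; fewer than 3 usable points is an error. The
    slope's sign is reported as-is — stability comparisons use |slope|.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size != v.size:
        raise ValueError("times and values must have equal length")
    if window is None:
        window = (float(t.min()), float(t.max()))
    t0, t1 = window
    if not t0 < t1:
        raise ValueError("window must satisfy t_start < t_end")
    sel = (t >= t0) & (t <= t1) & np.isfinite(v)
    if sel.sum() < 3:
        raise ValueError("need at least 3 finite points in the window")
    if np.ptp(v[sel]) == 0.0:
        return RateFit(0.0, float(v[sel][0]), (t0, t1), 1.0, int(sel.sum()))
    res = stats.linregress(t[sel], v[sel])
    return RateFit(float(res.slope), float(res.intercept), (t0, t1),
                   float(res.rvalue ** 2), int(sel.sum()))


def analyze_series(spectra, search_band: tuple = (430.0, 750.0),
                   fft_band: tuple | None = None,
                   rel_amp_floor: float = 0.02) -> DegradationSeries:
    """Degradation time series from a sequence of (t_min, spectrum) pairs.

    Per frame: rugate-peak wavelength (missing if no peak or edge peak) and
    EOT tracked from the t=0 dominant peak by nearest-neighbour continuity.
    A candidate whose fringe amplitude falls below ``rel_amp_floor`` times
    the initially tracked amplitude is rejected: once the film has fully
    dissolved only the smooth bare-substrate curvature remains, orders of
    magnitude weaker than genuine interference fringes, and the frame is
    flagged missing. The relative EOT change is anchored at the first
    finite EOT. Per-frame failures become NaN; the series never aborts.
    """
    spectra = list(spectra)
    if len(spectra) < 2:
        raise ValueError("need at least 2 time points")
    times = np.array([t for t, _ in spectra], dtype=float)
    peaks = np.full(times.size, np.nan)
    eots = np.full(times.size, np.nan)
    tracked = None
    amp0 = None
    for j, (_, spec) in enumerate(spectra):
        with warnings.catch_warnings():
            warnings.simplefilter("error", EdgePeakWarning)
            try:
                peaks[j] = find_rugate_peak(spec, search_band)
            except (NoPeakError, EdgePeakWarning):
                pass
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            try:
                res = compute_eot(spec, n_peaks=3, band=fft_band)
            except ValueError:
                continue
        if res.n_peaks == 0:
            continue
        if tracked is None:
            eots[j] = res.peak_positions[0]
            tracked = eots[j]
            amp0 = res.peak_amplitudes[0]
        else:
            i = int(np.argmin(np.abs(res.peak_positions - tracked)))
            if res.peak_amplitudes[i] < rel_amp_floor * amp0:
                continue
            eots[j] = res.peak_positions[i]
            tracked = eots[j]
    finite = np.isfinite(eots)
    rel = np.full(times.size, np.nan)
    if finite.any():
        eot0 = eots[np.flatnonzero(finite)[0]]
        rel[finite] = [(relative_eot_change(e, eot0)) for e in eots[finite]]
    return DegradationSeries(times, peaks, eots, rel)


def write_series_csv(path, series: DegradationSeries) -> None:
    series.to_frame().to_csv(path, index=False, float_format="%.6g")


def read_series_csv(path) -> DegradationSeries:
    df = pd.read_csv(path)
    return DegradationSeries(df["time_min"].to_numpy(float),
                             df["rugate_peak_nm"].to_numpy(float),
                             df["eot_um"].to_numpy(float),
                             df["rel_eot_pct"].to_numpy(float))
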