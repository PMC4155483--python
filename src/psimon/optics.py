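"""Forward optical model of porous-silicon rugate films.

A porous-Si rugate filter is a one-dimensional photonic crystal: the etch
waveform imprints a sinusoidal porosity depth profile p(z) = p_mean +
a*sin(2*pi*z/Lambda), which through the Bruggeman mixing rule becomes a
sinusoidal refractive-index profile. Normal-incidence reflectance of the
full film stack (optional polymer cap, rugate layer, bulk-Si substrate) is
computed with the characteristic-matrix (transfer-matrix) method, each
rugate period discretized into thin homogeneous sublayers.

The same module provides the degradation model (linear-in-time thickness
loss, porosity growth and skeleton oxidation, each clipped to its physical
range) and the spectroscopic liquid infiltration method (SLIM) inversion
that recovers porosity and thickness from effective-optical-thickness
measurements taken with two different pore-filling media.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .media import AIR, SILICA, SILICON, blend_media, bruggeman_index

__all__ = [
    "ReflectanceSpectrum",
    "PorousLayer",
    "UniformLayer",
    "LayerStack",
    "DegradationTrajectory",
    "default_wavelength_grid",
    "simulate_reflectance",
    "evolve_stack",
    "simulate_degradation_series",
    "slim_invert",
    "rugate_period_for_peak",
    "porosity_rate_for_shift",
    "write_spectrum",
    "read_spectrum",
    "InconsistentMeasurementsError",
]

SUBLAYERS_PER_PERIOD = 20  # convergence-tested against 40 (see tests)


class InconsistentMeasurementsError(ValueError):
    """SLIM EOT pair admits no (porosity, thickness) solution."""


def default_wavelength_grid(start: float = 400.0, stop: float = 1000.0,
                            step: float = 0.5) -> np.ndarray:
    """Working wavelength grid in nm (spectrometer range, inclusive)."""
    n = int(round((stop - start) / step))
    return start + step * np.arange(n + 1)


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """Sampled specular reflectance versus wavelength.

    ``wavelengths`` in nm, strictly increasing; ``reflectance`` unitless in
    [0, 1] (tiny numerical overshoot tolerated and clipped).
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self):
        lam = np.asarray(self.wavelengths, dtype=float)
        refl = np.asarray(self.reflectance, dtype=float)
        if lam.ndim != 1 or lam.size != refl.size:
            raise ValueError("wavelengths and reflectance must be equal-length 1-D")
        if lam.size < 1 or np.any(np.diff(lam) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(refl < -1e-9) or np.any(refl > 1.0 + 1e-9):
            raise ValueError("reflectance outside [0, 1]")
        object.__setattr__(self, "wavelengths", lam)
        object.__setattr__(self, "reflectance", np.clip(refl, 0.0, 1.0))

    def __len__(self):
        return self.wavelengths.size


@dataclass(frozen=True)
class PorousLayer:
    """Porous film with an optional sinusoidal (rugate) porosity modulation.

    ``porosity`` is the mean pore fraction, ``thickness`` in um; the
    depth profile is p(z) = porosity + rugate_amplitude*sin(2*pi*z/rugate_period)
    with ``rugate_period`` in um. ``skeleton`` and ``pore_fill`` are optical
    media (the skeleton may be a Si/SiO2 blend as oxidation proceeds).
    """

    porosity: float
    thickness: float
    skeleton: object = SILICON
    pore_fill: object = AIR
    rugate_amplitude: float = 0.0
    rugate_period: float = 0.0
    n_periods: int = 0

    def __post_init__(self):
        if not 0.0 <= self.porosity <= 1.0:
            raise ValueError("porosity must lie in [0, 1]")
        if self.thickness < 0:
            raise ValueError("thickness must be >= 0")
        if self.rugate_amplitude < 0:
            raise ValueError("rugate_amplitude must be >= 0")
        if self.rugate_amplitude > 0:
            if self.rugate_period <= 0:
                raise ValueError("rugate_period must be > 0 when modulated")
            lo = self.porosity - self.rugate_amplitude
            hi = self.porosity + self.rugate_amplitude
            if lo < -1e-9 or hi > 1.0 + 1e-9:
                raise ValueError("porosity +/- rugate_amplitude must stay in [0, 1]")

    @classmethod
    def rugate(cls, porosity, thickness, amplitude, period,
               skeleton=SILICON, pore_fill=AIR):
        """Rugate layer; thickness snapped to a whole number of periods."""
        n_per = max(1, int(round(thickness / period)))
        return cls(porosity, n_per * period, skeleton, pore_fill,
                   rugate_amplitude=amplitude, rugate_period=period,
                   n_periods=n_per)


@dataclass(frozen=True)
class UniformLayer:
    """Homogeneous (non-porous) overlayer, e.g. a spin-coated chitosan cap."""

    medium: object
    thickness: float  # um

    def __post_init__(self):
        if self.thickness < 0:
            raise ValueError("thickness must be >= 0")


@dataclass(frozen=True)
class LayerStack:
    """Film stack listed top (ambient side) to bottom (substrate side)."""

    layers: tuple
    substrate: object = SILICON
    ambient: object = AIR

    def __post_init__(self):
        object.__setattr__(self, "layers", tuple(self.layers))
        if not self.layers:
            raise ValueError("stack needs at least one layer")


# ---------------------------------------------------------------------------
# Transfer-matrix reflectance
# ---------------------------------------------------------------------------

def _char_matrices(n, delta):
    """Characteristic matrices, shape (..., 2, 2) complex, for slabs with
    index ``n`` and phase thickness ``delta`` (broadcast together)."""
    n = np.asarray(n, dtype=float)
    delta = np.asarray(delta, dtype=float)
    c = np.cos(delta)
    s = np.sin(delta)
    m = np.empty(np.broadcast(n, delta).shape + (2, 2), dtype=complex)
    m[..., 0, 0] = c
    m[..., 0, 1] = 1j * s / n
    m[..., 1, 0] = 1j * s * n
    m[..., 1, 1] = c
    return m


def _mat_power(m, k):
    """m**k for stacked 2x2 matrices via binary exponentiation."""
    result = np.broadcast_to(np.eye(2, dtype=complex), m.shape).copy()
    base = m
    while k:
        if k & 1:
            result = result @ base
        base = base @ base
        k >>= 1
    return result


def _porous_layer_matrix(layer: PorousLayer, lam: np.ndarray) -> np.ndarray:
    """Product characteristic matrix of one porous layer over grid ``lam``."""
    thick_nm = layer.thickness * 1e3
    if thick_nm == 0.0:
        return np.broadcast_to(np.eye(2, dtype=complex),
                               (lam.size, 2, 2)).copy()
    n_sk = np.asarray(layer.skeleton.index(lam), dtype=float)
    n_f = np.asarray(layer.pore_fill.index(lam), dtype=float)
    if layer.rugate_amplitude == 0.0:
        n_eff = np.sqrt(
            _bruggeman_eps_from_indices(layer.porosity, n_sk, n_f))
        return _char_matrices(n_eff, 2.0 * np.pi * n_eff * thick_nm / lam)

    period_nm = layer.rugate_period * 1e3
    dz = period_nm / SUBLAYERS_PER_PERIOD
    z_centers = (np.arange(SUBLAYERS_PER_PERIOD) + 0.5) * dz
    p_sub = layer.porosity + layer.rugate_amplitude * np.sin(
        2.0 * np.pi * z_centers / period_nm)
    p_sub = np.clip(p_sub, 0.0, 1.0)

    # (sublayer, wavelength) effective indices for one period
    eps = _bruggeman_eps_from_indices(p_sub[:, None], n_sk[None, :],
                                      n_f[None, :])
    n_sub = np.sqrt(eps)

    def section(thicknesses):
        mats = _char_matrices(
            n_sub, 2.0 * np.pi * n_sub * thicknesses[:, None] / lam[None, :])
        out = mats[0]
        for j in range(1, mats.shape[0]):
            out = out @ mats[j]
        return out

    full_periods = int(thick_nm // period_nm)
    remainder_nm = thick_nm - full_periods * period_nm
    m = np.broadcast_to(np.eye(2, dtype=complex), (lam.size, 2, 2)).copy()
    if full_periods:
        unit = section(np.full(SUBLAYERS_PER_PERIOD, dz))
        m = m @ _mat_power(unit, full_periods)
    if remainder_nm > 1e-9:
        n_rem = int(np.ceil(remainder_nm / dz))
        dz_rem = remainder_nm / n_rem
        z_rem = (np.arange(n_rem) + 0.5) * dz_rem
        p_rem = np.clip(layer.porosity + layer.rugate_amplitude
                        * np.sin(2.0 * np.pi * z_rem / period_nm), 0.0, 1.0)
        eps_r = _bruggeman_eps_from_indices(p_rem[:, None], n_sk[None, :],
                                            n_f[None, :])
        n_r = np.sqrt(eps_r)
        mats = _char_matrices(
            n_r, 2.0 * np.pi * n_r * dz_rem / lam[None, :])
        for j in range(mats.shape[0]):
            m = m @ mats[j]
    return m


def _bruggeman_eps_from_indices(porosity, n_sk, n_f):
    from .media import bruggeman_epsilon
    return bruggeman_epsilon(porosity, np.asarray(n_sk) ** 2,
                             np.asarray(n_f) ** 2)


def simulate_reflectance(stack: LayerStack, wavelengths=None) -> ReflectanceSpectrum:
    """Normal-incidence reflectance of ``stack`` on the given grid (nm).

    Rugate layers are discretized into ``SUBLAYERS_PER_PERIOD`` homogeneous
    sublayers per period; each sublayer's index comes from the Bruggeman
    rule. The spectrum shows the rugate stop band near
    2*n_eff(p_mean)*Lambda and Fabry-Perot fringes whose spacing in
    wavenumber is 1/(2nL).
    """
    lam = default_wavelength_grid() if wavelengths is None \
        else np.asarray(wavelengths, dtype=float)
    if lam.ndim != 1 or lam.size < 1 or np.any(np.diff(lam) <= 0):
        raise ValueError("wavelengths must be strictly increasing")

    m = np.broadcast_to(np.eye(2, dtype=complex), (lam.size, 2, 2)).copy()
    for layer in stack.layers:
        if isinstance(layer, PorousLayer):
            m = m @ _porous_layer_matrix(layer, lam)
        elif isinstance(layer, UniformLayer):
            if layer.thickness == 0.0:
                continue
            n = np.asarray(layer.medium.index(lam), dtype=float)
            delta = 2.0 * np.pi * n * (layer.thickness * 1e3) / lam
            m = m @ _char_matrices(n, delta)
        else:
            raise TypeError(f"unsupported layer type {type(layer).__name__}")

    n0 = np.asarray(stack.ambient.index(lam), dtype=float)
    ns = np.asarray(stack.substrate.index(lam), dtype=float)
    b = m[:, 0, 0] + m[:, 0, 1] * ns
    c = m[:, 1, 0] + m[:, 1, 1] * ns
    r = (n0 * b - c) / (n0 * b + c)
    return ReflectanceSpectrum(lam, np.abs(r) ** 2)


# ---------------------------------------------------------------------------
# Degradation model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DegradationTrajectory:
    """Linear-in-time degradation of the porous film.

    ``dissolution_rate`` removes physical thickness (um/min, floored at 0);
    ``porosity_rate`` thins the pore walls (porosity fraction/min, capped at
    1); ``oxidation_rate`` converts skeleton Si to SiO2 (fraction/min,
    capped at 1). ``overlayer_rate`` (um/min) erodes non-porous overlayers.
    ``t_grid`` is the observation schedule in minutes starting at 0.
    """

    dissolution_rate: float = 0.0
    porosity_rate: float = 0.0
    oxidation_rate: float = 0.0
    overlayer_rate: float = 0.0
    t_grid: np.ndarray = field(default_factory=lambda: 5.0 * np.arange(61))

    def __post_init__(self):
        for name in ("dissolution_rate", "porosity_rate", "oxidation_rate",
                     "overlayer_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        t = np.asarray(self.t_grid, dtype=float)
        if t.size == 0:
            raise ValueError("t_grid must be non-empty")
        if t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise ValueError("t_grid must strictly increase from 0")
        object.__setattr__(self, "t_grid", t)


def evolve_stack(stack: LayerStack, traj: DegradationTrajectory,
                 t: float) -> LayerStack:
    """Stack at elapsed time ``t`` minutes under trajectory ``traj``.

    Porous layers lose thickness at ``dissolution_rate``, gain porosity at
    ``porosity_rate`` and their skeleton blends Si -> SiO2 by the oxidized
    fraction; each quantity is clipped to its physical range. Once a
    layer's thickness reaches 0 it no longer contributes and the spectrum
    tends to the bare-substrate Fresnel response.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0:
        return stack
    new_layers = []
    ox = min(1.0, traj.oxidation_rate * t)
    for layer in stack.layers:
        if isinstance(layer, PorousLayer):
            thick = max(0.0, layer.thickness - traj.dissolution_rate * t)
            por = min(1.0, layer.porosity + traj.porosity_rate * t)
            amp = layer.rugate_amplitude
            if amp > 0:
                amp = max(0.0, min(amp, 1.0 - por, por))
            skel = layer.skeleton
            if ox > 0:
                skel = blend_media(layer.skeleton, SILICA, ox)
            new_layers.append(replace(layer, thickness=thick, porosity=por,
                                      rugate_amplitude=amp, skeleton=skel))
        elif isinstance(layer, UniformLayer):
            thick = max(0.0, layer.thickness - traj.overlayer_rate * t)
            new_layers.append(replace(layer, thickness=thick))
        else:
            new_layers.append(layer)
    return replace(stack, layers=tuple(new_layers))


def simulate_degradation_series(stack: LayerStack, traj: DegradationTrajectory,
                                wavelengths=None, noise_sd: float = 0.0,
                                seed: int | None = None):
    """One reflectance spectrum per time in ``traj.t_grid``.

    Optional additive Gaussian reflectance noise (std ``noise_sd``, clipped
    back into [0, 1]) drawn from a generator seeded with ``seed``; with the
    same seed the output is bit-identical across runs.
    """
    lam = default_wavelength_grid() if wavelengths is None \
        else np.asarray(wavelengths, dtype=float)
    rng = np.random.default_rng(seed)
    out = []
    for t in traj.t_grid:
        spec = simulate_reflectance(evolve_stack(stack, traj, float(t)), lam)
        if noise_sd > 0:
            noisy = np.clip(spec.reflectance
                            + rng.normal(0.0, noise_sd, lam.size), 0.0, 1.0)
            spec = ReflectanceSpectrum(lam, noisy)
        out.append((float(t), spec))
    return out


# ---------------------------------------------------------------------------
# SLIM inversion
# ---------------------------------------------------------------------------

def slim_invert(eot_air: float, eot_fill: float, skeleton=SILICON,
                fill=None, wavelength_ref: float = 700.0):
    """Porosity and thickness from an air/liquid EOT pair (SLIM).

    EOT = 2*n_eff*L is measured twice, with empty pores (``eot_air``, um)
    and with pores infiltrated by a liquid of known index (``eot_fill``,
    um). Since L is common, the porosity solves

        eot_air / n_eff(p; air) = eot_fill / n_eff(p; fill)

    by bracketed root search on p in (0, 1); the thickness follows.
    Returns ``(porosity, thickness_um)``.
    """
    from .media import ETHANOL
    if fill is None:
        fill = ETHANOL
    n_fill = float(fill.index(wavelength_ref))
    n_air = float(AIR.index(wavelength_ref))
    if abs(n_fill - n_air) < 1e-9:
        raise InconsistentMeasurementsError(
            "infiltration medium must differ from air")
    if eot_air <= 0:
        raise InconsistentMeasurementsError("eot_air must be > 0")
    if n_fill > n_air and eot_fill <= eot_air:
        raise InconsistentMeasurementsError(
            "infiltration by a higher-index liquid must raise the EOT")

    def mismatch(p):
        na = bruggeman_index(p, skeleton, AIR, wavelength_ref)
        nf = bruggeman_index(p, skeleton, fill, wavelength_ref)
        return eot_air / na - eot_fill / nf

    lo, hi = 1e-12, 1.0 - 1e-12
    f_lo, f_hi = mismatch(lo), mismatch(hi)
    if f_lo == 0.0:
        p = lo
    elif f_hi == 0.0:
        p = hi
    elif f_lo * f_hi > 0:
        raise InconsistentMeasurementsError(
            "EOT pair admits no porosity in (0, 1)")
    else:
        p = brentq(mismatch, lo, hi, xtol=1e-15, rtol=8.9e-16)
    thickness = eot_air / (2.0 * bruggeman_index(p, skeleton, AIR,
                                                 wavelength_ref))
    return float(p), float(thickness)


# ---------------------------------------------------------------------------
# Design helpers
# ---------------------------------------------------------------------------

def rugate_period_for_peak(peak_nm: float, porosity: float, skeleton=SILICON,
                           pore_fill=AIR) -> float:
    """Rugate spatial period (um) placing the stop band at ``peak_nm``.

    Uses the first-order Bragg condition lambda_peak = 2*n_eff(p_mean)*Lambda
    with n_eff evaluated at the target wavelength.
    """
    n_eff = bruggeman_index(porosity, skeleton, pore_fill, peak_nm)
    return peak_nm / (2.0 * n_eff) * 1e-3


def porosity_rate_for_shift(shift_nm_per_min: float, porosity: float,
                            period_um: float, skeleton=SILICON,
                            pore_fill=AIR, wavelength_ref=None) -> float:
    """Porosity rate (fraction/min) giving a target stop-band blue shift.

    Linearizes lambda_peak(p) = 2*n_eff(p)*Lambda around the starting
    porosity: k_p = shift / (2*Lambda*|dn_eff/dp|).
    """
    period_nm = period_um * 1e3
    if wavelength_ref is None:
        wavelength_ref = 2.0 * bruggeman_index(porosity, skeleton, pore_fill,
                                               600.0) * period_nm
    dp = 1e-4
    dn = (bruggeman_index(porosity + dp, skeleton, pore_fill, wavelength_ref)
          - bruggeman_index(porosity - dp, skeleton, pore_fill,
                            wavelength_ref)) / (2 * dp)
    if dn == 0:
        raise ValueError("stop band insensitive to porosity")
    return shift_nm_per_min / (2.0 * period_nm * abs(dn))


# ---------------------------------------------------------------------------
# Spectrum file I/O
# ---------------------------------------------------------------------------

def write_spectrum(path, spec: ReflectanceSpectrum) -> None:
    """Two-column text file (wavelength_nm, reflectance), 6 sig. digits."""
    with open(path, "w") as fh:
        fh.write("wavelength_nm\treflectance\n")
        for lam, r in zip(spec.wavelengths, spec.reflectance):
            fh.write(f"{lam:.6g}\t{r:.6g}\n")


def read_spectrum(path) -> ReflectanceSpectrum:
    """Read a two-column delimited spectrum; a header line is optional."""
    data = np.genfromtxt(path, names=None, dtype=float, skip_header=0,
                         invalid_raise=False)
    data = np.atleast_2d(data)
    data = data[~np.isnan(data).any(axis=1)]
    if data.shape[1] < 2 or data.shape[0] < 2:
        raise ValueError(f"{path}: not a two-column spectrum file")
    return ReflectanceSpectrum(data[:, 0], data[:, 1])
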