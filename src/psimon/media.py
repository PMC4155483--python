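"""Optical media and the Bruggeman effective-medium approximation.

All refractive indices are real-valued (absorption is neglected) and follow
a two-term Cauchy dispersion n(lambda) = A + B / lambda**2 with lambda in nm.
The composite index of the porous skeleton + pore-filling phase is obtained
from the self-consistent two-component Bruggeman mixing rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OpticalMedium",
    "CauchyMedium",
    "blend_media",
    "bruggeman_epsilon",
    "bruggeman_index",
    "AIR",
    "SILICON",
    "SILICA",
    "ETHANOL",
    "BUFFER",
    "CHITOSAN",
]


class BruggemanRootError(ArithmeticError):
    """Raised when no physical Bruggeman root exists between the components."""


@dataclass(frozen=True)
class CauchyMedium:
    """Non-absorbing medium with Cauchy dispersion n = A + B/lambda^2.

    Parameters
    ----------
    name : str
        Human-readable label ("Si", "air", ...).
    A : float
        Long-wavelength limit of the refractive index (dimensionless).
    B : float
        Dispersion coefficient in nm^2; B > 0 gives normal dispersion
        (higher index in the blue).
    """

    name: str
    A: float
    B: float = 0.0

    def index(self, wavelength_nm):
        """Refractive index at the given wavelength(s) in nm."""
        lam = np.asarray(wavelength_nm, dtype=float)
        n = self.A + self.B / lam**2
        return n if n.ndim else float(n)

    def __call__(self, wavelength_nm):
        return self.index(wavelength_nm)


# Public alias: anything exposing .index(wavelength_nm) is an optical medium.
OpticalMedium = CauchyMedium


# Default constants (configuration-level, overridable through the YAML
# config): silicon with mild visible dispersion, thermal oxide, common fills.
AIR = CauchyMedium("air", 1.0)
SILICON = CauchyMedium("Si", 3.42, 2.0e4)
SILICA = CauchyMedium("SiO2", 1.46)
ETHANOL = CauchyMedium("ethanol", 1.36)
BUFFER = CauchyMedium("buffer", 1.35)
CHITOSAN = CauchyMedium("chitosan", 1.54)


@dataclass(frozen=True)
class _BlendMedium:
    """Volume-weighted dielectric blend of two media (used for oxidation)."""

    name: str
    first: CauchyMedium
    second: CauchyMedium
    fraction_second: float

    def index(self, wavelength_nm):
        e1 = np.asarray(self.first.index(wavelength_nm), dtype=float) ** 2
        e2 = np.asarray(self.second.index(wavelength_nm), dtype=float) ** 2
        f = self.fraction_second
        n = np.sqrt((1.0 - f) * e1 + f * e2)
        return n if n.ndim else float(n)

    def __call__(self, wavelength_nm):
        return self.index(wavelength_nm)


def blend_media(first, second, fraction_second: float, name: str | None = None):
    """Medium whose dielectric function linearly blends ``first``->``second``.

    Models progressive chemical conversion of the skeleton (Si -> SiO2 during
    oxidation) at converted volume fraction ``fraction_second``.
    """
    if not 0.0 <= fraction_second <= 1.0:
        raise ValueError("fraction_second must lie in [0, 1]")
    if fraction_second == 0.0:
        return first
    if fraction_second == 1.0:
        return second
    label = name or f"{first.name}+{second.name}({fraction_second:.3f})"
    return _BlendMedium(label, first, second, fraction_second)


def bruggeman_epsilon(porosity, eps_skeleton, eps_fill):
    """Effective dielectric constant of a two-phase composite.

    Solves the self-consistent condition

        (1-p) (eps_sk - eps)/(eps_sk + 2 eps)
          + p (eps_f - eps)/(eps_f + 2 eps) = 0

    for the effective ``eps``. Clearing denominators gives the quadratic
    ``-2 eps^2 + b eps + eps_sk eps_f = 0`` with
    ``b = (1-p)(2 eps_sk - eps_f) + p (2 eps_f - eps_sk)``; the unique
    positive root is the physical branch (it reduces to the pure component
    at p = 0 and p = 1 and lies between the two dielectric constants).

    All arguments broadcast; returns an array (or scalar) of eps values.
    """
    p = np.asarray(porosity, dtype=float)
    if np.any(p < -1e-12) or np.any(p > 1.0 + 1e-12):
        raise ValueError("porosity must lie in [0, 1]")
    p = np.clip(p, 0.0, 1.0)
    e_sk = np.asarray(eps_skeleton, dtype=float)
    e_f = np.asarray(eps_fill, dtype=float)
    b = (1.0 - p) * (2.0 * e_sk - e_f) + p * (2.0 * e_f - e_sk)
    disc = b * b + 8.0 * e_sk * e_f
    if np.any(disc < 0):
        raise BruggemanRootError("no real Bruggeman root")
    eps = (b + np.sqrt(disc)) / 4.0
    lo = np.minimum(e_sk, e_f)
    hi = np.maximum(e_sk, e_f)
    if np.any(eps < lo - 1e-9) or np.any(eps > hi + 1e-9):
        raise BruggemanRootError("Bruggeman root outside the component bracket")
    return eps


def bruggeman_index(porosity, skeleton, fill, wavelength_nm):
    """Effective refractive index of a porous composite at ``wavelength_nm``.

    ``porosity`` is the pore volume fraction occupied by ``fill``; the solid
    fraction is ``skeleton``. Broadcasts over porosity and wavelength.
    """
    n_sk = np.asarray(skeleton.index(wavelength_nm), dtype=float)
    n_f = np.asarray(fill.index(wavelength_nm), dtype=float)
    eps = bruggeman_epsilon(porosity, n_sk**2, n_f**2)
    n = np.sqrt(eps)
    return n if np.ndim(n) else float(n)
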