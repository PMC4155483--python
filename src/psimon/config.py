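"""YAML configuration for the simulation/analysis pipeline.

One flat-schema config file drives every stage: the physical sample, the
degradation trajectory, the camera model, the analysis bands/windows and
the fixture-image geometry. Unknown keys are rejected with the offending
key named, so typos fail loudly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .color import CameraModel
from .media import (AIR, BUFFER, CHITOSAN, ETHANOL, SILICA, SILICON,
                    CauchyMedium)
from .optics import (DegradationTrajectory, LayerStack, PorousLayer,
                     UniformLayer, rugate_period_for_peak)

__all__ = ["PipelineConfig", "ConfigError", "load_config", "bundled_config"]

_MEDIA = {"air": AIR, "Si": SILICON, "SiO2": SILICA, "ethanol": ETHANOL,
          "buffer": BUFFER, "chitosan": CHITOSAN}


class ConfigError(ValueError):
    """Malformed or unknown configuration content."""


def _medium(spec, label):
    if isinstance(spec, str):
        try:
            return _MEDIA[spec]
        except KeyError:
            raise ConfigError(
                f"{label}: unknown medium {spec!r} "
                f"(known: {sorted(_MEDIA)})") from None
    if isinstance(spec, dict):
        extra = set(spec) - {"name", "A", "B"}
        if extra:
            raise ConfigError(f"{label}: unknown keys {sorted(extra)}")
        return CauchyMedium(spec.get("name", label), float(spec["A"]),
                            float(spec.get("B", 0.0)))
    raise ConfigError(f"{label}: expected medium name or Cauchy dict")


def _take(d: dict, label: str, **defaults):
    extra = set(d) - set(defaults)
    if extra:
        raise ConfigError(f"{label}: unknown keys {sorted(extra)}")
    return {k: d.get(k, v) for k, v in defaults.items()}


@dataclass
class PipelineConfig:
    """Fully resolved pipeline configuration."""

    name: str
    stack: LayerStack
    trajectory: DegradationTrajectory
    camera: CameraModel
    wavelengths: np.ndarray
    noise_sd: float
    seed: int | None
    search_band: tuple
    fft_band: tuple | None
    rate_window: tuple
    fixture: dict


def load_config(source) -> PipelineConfig:
    """Parse a YAML config file (path or mapping) into pipeline objects."""
    if isinstance(source, dict):
        raw = source
    else:
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    top = _take(raw, "config", name="sample", seed=None, wavelengths={},
                sample={}, degradation={}, camera={}, analysis={}, fixture={})

    wl = _take(top["wavelengths"], "wavelengths", start=400.0, stop=1000.0,
               step=0.5)
    n = int(round((wl["stop"] - wl["start"]) / wl["step"]))
    lam = wl["start"] + wl["step"] * np.arange(n + 1)

    s = _take(top["sample"], "sample", porosity=0.534, thickness_um=22.8,
              rugate_amplitude=0.015, rugate_peak_nm=593.0,
              rugate_period_um=None, skeleton="Si", pore_fill="buffer",
              ambient="buffer", substrate="Si", overlayer=None)
    skeleton = _medium(s["skeleton"], "sample.skeleton")
    fill = _medium(s["pore_fill"], "sample.pore_fill")
    period = s["rugate_period_um"]
    if period is None:
        period = rugate_period_for_peak(float(s["rugate_peak_nm"]),
                                        float(s["porosity"]), skeleton, fill)
    layers = []
    if s["overlayer"]:
        o = _take(s["overlayer"], "sample.overlayer", medium="chitosan",
                  thickness_um=0.0)
        if o["thickness_um"] > 0:
            layers.append(UniformLayer(_medium(o["medium"],
                                               "sample.overlayer.medium"),
                                       float(o["thickness_um"])))
    layers.append(PorousLayer.rugate(float(s["porosity"]),
                                     float(s["thickness_um"]),
                                     float(s["rugate_amplitude"]),
                                     float(period), skeleton, fill))
    stack = LayerStack(layers, substrate=_medium(s["substrate"],
                                                 "sample.substrate"),
                       ambient=_medium(s["ambient"], "sample.ambient"))

    d = _take(top["degradation"], "degradation", dissolution_rate=0.0,
              porosity_rate=0.0, oxidation_rate=0.0, overlayer_rate=0.0,
              rugate_shift_nm_per_min=None, t_end_min=300.0, t_step_min=5.0,
              noise_sd=0.0)
    kp = float(d["porosity_rate"])
    if d["rugate_shift_nm_per_min"] is not None:
        from .optics import porosity_rate_for_shift
        kp = porosity_rate_for_shift(float(d["rugate_shift_nm_per_min"]),
                                     float(s["porosity"]), float(period),
                                     skeleton, fill)
    n_t = int(math.floor(d["t_end_min"] / d["t_step_min"]))
    traj = DegradationTrajectory(
        dissolution_rate=float(d["dissolution_rate"]), porosity_rate=kp,
        oxidation_rate=float(d["oxidation_rate"]),
        overlayer_rate=float(d["overlayer_rate"]),
        t_grid=d["t_step_min"] * np.arange(n_t + 1))

    c = _take(top["camera"], "camera", channel_centers=(600.0, 540.0, 465.0),
              channel_fwhm=80.0, illuminant_k=3000.0, white_balance="none",
              exposure=0.9, gamma="srgb")
    camera = CameraModel(tuple(float(x) for x in c["channel_centers"]),
                         float(c["channel_fwhm"]), float(c["illuminant_k"]),
                         str(c["white_balance"]), float(c["exposure"]),
                         c["gamma"], wavelengths=lam)

    a = _take(top["analysis"], "analysis", search_band=(430.0, 750.0),
              fft_band=(650.0, 1000.0), rate_window=(0.0, 25.0))
    fx = _take(top["fixture"], "fixture", noise_sd=0.0, height=144, width=192,
               roi_radius=40, image_format="png")

    return PipelineConfig(
        name=str(top["name"]), stack=stack, trajectory=traj, camera=camera,
        wavelengths=lam, noise_sd=float(d["noise_sd"]),
        seed=None if top["seed"] is None else int(top["seed"]),
        search_band=tuple(a["search_band"]),
        fft_band=None if a["fft_band"] in (None, "none")
        else tuple(a["fft_band"]),
        rate_window=tuple(a["rate_window"]), fixture=fx)


def bundled_config(name: str) -> PipelineConfig:
    """Load one of the packaged sample configs ("fpsi" or "psi_ch")."""
    ref = resources.files("psimon") / "configs" / f"{name}.yaml"
    with resources.as_file(ref) as path:
        return load_config(path)
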