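"""End-to-end stages tying the simulator, camera and analysis together.

These functions are the programmatic core of the command-line interface:
simulate a configured sample (spectra + rendered RGB + fixture images),
analyze spectra/RGB back into degradation series, and assemble stability
reports. Everything is deterministic given the config and seed.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .color import RGBSeries, compute_h_parameter, render_rgb
from .config import PipelineConfig
from .imaging import generate_fixture_stack
from .optics import simulate_degradation_series, write_spectrum
from .spectral import analyze_series, write_series_csv

__all__ = ["simulate_sample", "write_simulation", "analyze_sample",
           "read_spectra_dir"]


def simulate_sample(cfg: PipelineConfig, seed: int | None = None):
    """Spectra and rendered RGB series for a configured sample.

    Returns ``(series, rgb_series)`` where ``series`` is a list of
    ``(t_min, ReflectanceSpectrum)``. ``seed`` overrides the config seed
    for the reflectance noise draw.
    """
    use_seed = cfg.seed if seed is None else seed
    series = simulate_degradation_series(
        cfg.stack, cfg.trajectory, wavelengths=cfg.wavelengths,
        noise_sd=cfg.noise_sd, seed=use_seed)
    # ROI channel means over ~1e5 pixels resolve well below one 8-bit
    # count, so the rendered series keeps float precision; per-pixel
    # quantization is applied when fixture images are written.
    rgb = np.array([render_rgb(spec, cfg.camera, quantize=False)
                    for _, spec in series], dtype=float)
    return series, RGBSeries(cfg.trajectory.t_grid.copy(), rgb)


def write_simulation(cfg: PipelineConfig, out_dir, seed: int | None = None):
    """Run a simulation and write spectra, RGB CSV and the fixture stack.

    Layout: ``spectra/spec_0000.txt`` + ``spectra/manifest.csv``,
    ``rgb_series.csv`` and ``frames/`` (images, masks, manifest).
    """
    out_dir = os.fspath(out_dir)
    series, rgbs = simulate_sample(cfg, seed)
    spec_dir = os.path.join(out_dir, "spectra")
    os.makedirs(spec_dir, exist_ok=True)
    names = []
    for j, (t, spec) in enumerate(series):
        name = f"spec_{j:04d}.txt"
        write_spectrum(os.path.join(spec_dir, name), spec)
        names.append(name)
    pd.DataFrame({"filename": names,
                  "time_min": [t for t, _ in series]}).to_csv(
        os.path.join(spec_dir, "manifest.csv"), index=False)
    rgbs.to_frame().to_csv(os.path.join(out_dir, "rgb_series.csv"),
                           index=False, float_format="%.6g")
    use_seed = cfg.seed if seed is None else seed
    fx = cfg.fixture
    generate_fixture_stack(
        rgbs, os.path.join(out_dir, "frames"), noise_sd=fx["noise_sd"],
        seed=use_seed, shape=(fx["height"], fx["width"]),
        roi_radius=fx["roi_radius"], image_format=fx["image_format"])
    return series, rgbs


def read_spectra_dir(spectra_dir):
    """Load ``(t, spectrum)`` pairs written by ``write_simulation``."""
    from .optics import read_spectrum
    spectra_dir = os.fspath(spectra_dir)
    manifest = pd.read_csv(os.path.join(spectra_dir, "manifest.csv"))
    return [(float(t), read_spectrum(os.path.join(spectra_dir, f)))
            for f, t in zip(manifest["filename"], manifest["time_min"])]


def analyze_sample(spectra, cfg: PipelineConfig, rgb_series=None,
                   out_dir=None):
    """Degradation series (and hue series, if RGB given) for one sample.

    ``spectra`` is a list of ``(t, spectrum)``; ``rgb_series`` an optional
    ``RGBSeries``. When ``out_dir`` is given the series are written as
    ``degradation_series.csv`` / ``hue_series.csv``.
    """
    deg = analyze_series(spectra, search_band=cfg.search_band,
                         fft_band=cfg.fft_band)
    hue = compute_h_parameter(rgb_series) if rgb_series is not None else None
    if out_dir is not None:
        out_dir = os.fspath(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        write_series_csv(os.path.join(out_dir, "degradation_series.csv"), deg)
        if hue is not None:
            hue.to_frame().to_csv(os.path.join(out_dir, "hue_series.csv"),
                                  index=False, float_format="%.6g")
    return deg, hue
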