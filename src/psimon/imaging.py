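"""Time-lapse image stacks: fixture generation and mean-RGB extraction.

A monitored experiment is a directory of 8-bit RGB frames plus two
single-channel mask images (region of interest over the sample, and a
reference patch on a surface that does not degrade) and a manifest CSV
mapping each frame file to its acquisition time. The extraction step
optionally applies the reference-patch balance to each frame and then
averages the ROI pixels per channel.

The fixture generator is the inverse path: it renders synthetic frames
(uniform ROI color + optional Gaussian pixel noise, neutral-gray reference
patch, dark background) from an RGB series, so the whole imaging pipeline
can be exercised without laboratory photographs. Fixtures are written as
PNG for byte-determinism; a JPEG mode exists to exercise lossy-compression
robustness.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .color import RGBSeries, reference_balance

__all__ = ["MaskedStack", "extract_rgb_series", "generate_fixture_stack"]


@dataclass
class MaskedStack:
    """Frame files, acquisition times and the ROI / reference masks."""

    frame_paths: list
    times: np.ndarray
    roi_mask: np.ndarray        # bool raster, frame-shaped
    reference_region: np.ndarray

    def __post_init__(self):
        if not self.frame_paths:
            raise ValueError("stack needs at least one frame")
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size != len(self.frame_paths):
            raise ValueError("one time per frame required")
        self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
        self.reference_region = np.asarray(self.reference_region, dtype=bool)
        if self.roi_mask.shape != self.reference_region.shape:
            raise ValueError("masks must share dimensions")
        if not self.roi_mask.any():
            raise ValueError("ROI mask is empty")
        if not self.reference_region.any():
            raise ValueError("reference region is empty")
        if (self.roi_mask & self.reference_region).any():
            raise ValueError("ROI and reference region must be disjoint")

    @classmethod
    def from_dir(cls, directory) -> "MaskedStack":
        """Load a stack laid out as written by ``generate_fixture_stack``."""
        directory = os.fspath(directory)
        manifest = pd.read_csv(os.path.join(directory, "manifest.csv"))
        paths = [os.path.join(directory, f) for f in manifest["filename"]]
        roi = iio.imread(os.path.join(directory, "mask_roi.png")) > 127
        ref = iio.imread(os.path.join(directory, "mask_ref.png")) > 127
        return cls(paths, manifest["time_min"].to_numpy(float), roi, ref)


def extract_rgb_series(stack: MaskedStack, balance: bool = True) -> RGBSeries:
    """Per-frame mean ROI RGB, optionally after reference-patch balancing.

    With ``balance`` the per-frame mean RGB of the reference region defines
    a per-channel scaling that maps the patch to neutral gray before the
    ROI pixels are averaged. Frames that cannot be read or whose
    dimensions differ from the mask raise an error naming the file.
    """
    values = np.empty((len(stack.frame_paths), 3))
    for j, path in enumerate(stack.frame_paths):
        try:
            frame = iio.imread(path)
        except Exception as exc:
            raise IOError(f"cannot read frame {path}: {exc}") from exc
        if frame.ndim != 3 or frame.shape[2] < 3:
            raise ValueError(f"frame {path} is not RGB")
        if frame.shape[:2] != stack.roi_mask.shape:
            raise ValueError(
                f"frame {path} has shape {frame.shape[:2]}, mask is "
                f"{stack.roi_mask.shape}")
        frame = frame[:, :, :3].astype(float)
        if balance:
            ref_mean = frame[stack.reference_region].mean(axis=0)
            if np.any(ref_mean <= 0):
                raise ValueError(f"frame {path}: reference patch has a zero channel")
            scale = ref_mean.mean() / ref_mean
            frame = np.clip(frame * scale, 0.0, 255.0)
        values[j] = frame[stack.roi_mask].mean(axis=0)
    return RGBSeries(stack.times.copy(), values)


def generate_fixture_stack(rendered: RGBSeries, out_dir, noise_sd: float = 0.0,
                           seed: int | None = None, shape: tuple = (144, 192),
                           roi_radius: int = 40, reference_gray: float = 200.0,
                           background=(30.0, 30.0, 40.0),
                           image_format: str = "png") -> MaskedStack:
    """Write a synthetic time-lapse stack for an RGB series.

    Each frame contains a centered disc ROI filled with that time point's
    rendered triplet (plus optional zero-mean Gaussian pixel noise of std
    ``noise_sd``, seeded and therefore reproducible), a neutral-gray
    reference rectangle in the top-left corner, and a distinct dark
    background. Also writes ``mask_roi.png``, ``mask_ref.png`` (0/255
    single channel) and ``manifest.csv`` (filename, time_min).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    height, width = shape
    yy, xx = np.mgrid[:height, :width]
    roi = (yy - height / 2) ** 2 + (xx - width / 2) ** 2 <= roi_radius**2
    ref = np.zeros(shape, dtype=bool)
    ref[2:height // 6 + 2, 2:width // 4 + 2] = True
    if (roi & ref).any():
        raise ValueError("ROI radius too large: overlaps the reference patch")

    iio.imwrite(os.path.join(out_dir, "mask_roi.png"),
                (roi * 255).astype(np.uint8))
    iio.imwrite(os.path.join(out_dir, "mask_ref.png"),
                (ref * 255).astype(np.uint8))

    rng = np.random.default_rng(seed)
    ext = image_format.lower()
    if ext not in ("png", "jpeg", "jpg", "tiff"):
        raise ValueError(f"unsupported image format {image_format!r}")
    names = []
    for j, rgb in enumerate(rendered.rgb):
        frame = np.empty(shape + (3,), dtype=float)
        frame[:] = np.asarray(background, dtype=float)
        frame[ref] = reference_gray
        roi_px = np.broadcast_to(rgb, (int(roi.sum()), 3)).copy()
        if noise_sd > 0:
            roi_px += rng.normal(0.0, noise_sd, roi_px.shape)
        frame[roi] = roi_px
        name = f"frame_{j:04d}.{ext}"
        iio.imwrite(os.path.join(out_dir, name),
                    np.clip(np.round(frame), 0, 255).astype(np.uint8))
        names.append(name)
    pd.DataFrame({"filename": names, "time_min": rendered.times}).to_csv(
        os.path.join(out_dir, "manifest.csv"), index=False)
    return MaskedStack([os.path.join(out_dir, n) for n in names],
                       rendered.times.copy(), roi, ref)
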