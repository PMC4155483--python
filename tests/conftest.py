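import numpy as np
import pytest

from psimon import (CameraModel, RGBSeries, compute_h_parameter,
                    render_rgb, simulate_degradation_series)
from psimon.config import bundled_config
from psimon.pipeline import analyze_sample, simulate_sample


@pytest.fixture(scope="session")
def fpsi_cfg():
    return bundled_config("fpsi")


@pytest.fixture(scope="session")
def psich_cfg():
    return bundled_config("psi_ch")


@pytest.fixture(scope="session")
def full_cfg():
    """Complete-degradation scenario (pore walls gone at 100 min)."""
    return bundled_config("fpsi_full")


@pytest.fixture(scope="session")
def full_run(full_cfg):
    """(spectra, rgb, degradation series, hue series) for the
    complete-degradation scenario; shared because the simulation is the
    most expensive fixture in the suite."""
    spectra, rgbs = simulate_sample(full_cfg)
    deg, hue = analyze_sample(spectra, full_cfg, rgbs)
    return spectra, rgbs, deg, hue


@pytest.fixture(scope="session")
def fpsi_run(fpsi_cfg):
    spectra, rgbs = simulate_sample(fpsi_cfg)
    deg, hue = analyze_sample(spectra, fpsi_cfg, rgbs)
    return spectra, rgbs, deg, hue


@pytest.fixture(scope="session")
def psich_run(psich_cfg):
    spectra, rgbs = simulate_sample(psich_cfg)
    deg, hue = analyze_sample(spectra, psich_cfg, rgbs)
    return spectra, rgbs, deg, hue
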