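"""Shared fixtures: small fast simulation configs and tiny spectra."""

import numpy as np
import pytest

from siapca import AxisCalibration, SimulationConfig, Spectrum2D


def small_axes():
    axis_h = AxisCalibration(n_points=64, spectral_width=5.0, ppm_first=11.0)
    axis_n = AxisCalibration(n_points=48, spectral_width=30.0, ppm_first=135.0, obs_mhz=70.95)
    return axis_h, axis_n


@pytest.fixture
def small_config():
    """A scaled-down experiment (64 x 48 grid, 20 peaks, 2 positions) that
    keeps every qualitative feature of the default conditions."""
    axis_h, axis_n = small_axes()
    return SimulationConfig(
        axis_h=axis_h,
        axis_n=axis_n,
        n_peaks=20,
        profile={1: ("G", "U", "C", "A"), 2: ("A", "C", "G", "U")},
        seed=7,
    )


@pytest.fixture
def noiseless_small_config(small_config):
    from dataclasses import replace

    return replace(small_config, noise_sd=0.0, scale_jitter_sd=0.0)


@pytest.fixture
def tiny_spectrum():
    rng = np.random.default_rng(0)
    axis_h, axis_n = small_axes()
    return Spectrum2D(
        intensities=rng.normal(size=(64, 48)),
        axis_h=axis_h,
        axis_n=axis_n,
        label="free",
    )
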