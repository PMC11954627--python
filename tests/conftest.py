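"""Shared fixtures: small synthetic scenes reused across the suite."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from mucoprofiler.scene import (
    ChannelModel,
    IntensityFn,
    default_scene_config,
    generate_scene,
)
from mucoprofiler.experiment import compact_scene_config


@pytest.fixture(scope="session")
def default_scene():
    """One reference 512x512 scene at default noise (DAPI + MUC2 + EUB338)."""
    cfg = default_scene_config()
    cfg.seed = 1
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def clean_mucus_scene():
    """Zero-noise, debris-free scene with a pure Gaussian mucus peak at 11 um.

    Rendered at 0.25 um/pixel so distance quantization does not dominate the
    comparison against the analytic intensity curve.
    """
    cfg = compact_scene_config()
    cfg.pixel_size = 0.25
    cfg.image_shape = (640, 192)
    cfg.channels = [
        ChannelModel(
            name="MUC2",
            kind="diffuse",
            intensity_fn=IntensityFn("gaussian_peak", {"center_um": 11.0, "sd_um": 4.0}),
            amplitude=20.0,
        )
    ]
    cfg.debris.count = 0
    cfg.noise.gaussian_sd = 0.0
    cfg.noise.poisson_gain = 0.0
    cfg.seed = 5
    return generate_scene(cfg)


def make_zero_noise_config(**overrides):
    cfg = compact_scene_config(**overrides)
    cfg.noise.gaussian_sd = 0.0
    cfg.noise.poisson_gain = 0.0
    return cfg


@pytest.fixture
def zero_noise_config():
    return make_zero_noise_config()
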