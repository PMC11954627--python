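"""Synthetic scene generator: determinism, rendering consistency, point process."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from mucoprofiler.errors import ConfigurationError
from mucoprofiler.profiles import bin_profile, compute_distance_field
from mucoprofiler.scene import (
    BoundaryGeometry,
    ChannelModel,
    DebrisSimParams,
    IntensityFn,
    NoiseParams,
    default_scene_config,
    generate_scene,
    make_group_experiment,
)
from tests.conftest import make_zero_noise_config


def test_seeded_determinism_bit_identical():
    cfg1 = default_scene_config()
    cfg1.seed = 42
    cfg2 = default_scene_config()
    cfg2.seed = 42
    img1, truth1 = generate_scene(cfg1)
    img2, truth2 = generate_scene(cfg2)
    assert img1.data.tobytes() == img2.data.tobytes()
    assert np.array_equal(truth1.boundary_coords, truth2.boundary_coords)
    assert np.array_equal(truth1.debris_mask, truth2.debris_mask)


def test_different_seed_changes_noise():
    cfg1 = default_scene_config()
    cfg1.seed = 1
    cfg2 = default_scene_config()
    cfg2.seed = 2
    img1, _ = generate_scene(cfg1)
    img2, _ = generate_scene(cfg2)
    assert not np.array_equal(img1.data, img2.data)


def test_flat_field_constant_channel():
    """Zero noise + constant intensity 5 on [0, 50) um -> every such pixel is 5."""
    cfg = make_zero_noise_config()
    cfg.channels = [
        ChannelModel(
            name="flat",
            kind="diffuse",
            intensity_fn=IntensityFn("constant", {"lo_um": 0.0, "hi_um": 50.0}),
            amplitude=5.0,
        )
    ]
    cfg.debris.count = 0
    img, truth = generate_scene(cfg)
    d = compute_distance_field(truth.boundary, img.shape, img.pixel_size).values
    plane = img.channel("flat")
    sel = (d >= 0) & (d < 50)
    assert np.all(plane[sel] == 5.0)
    assert np.all(plane[d >= 50] == 0.0)
    assert np.all(plane[d < 0] == 0.0)


def test_diffuse_rendering_matches_intensity_fn_exactly(clean_mucus_scene):
    """Noise off: pixel value at signed distance d equals amplitude * fn(d)."""
    img, truth = clean_mucus_scene
    d = compute_distance_field(truth.boundary, img.shape, img.pixel_size).values
    expected = truth.expected_intensity("MUC2", d)
    np.testing.assert_array_equal(img.channel("MUC2"), expected)


def test_punctate_rate_chi_square():
    """Puncta counts per 10-um distance band follow the configured constant rate."""
    cfg = make_zero_noise_config()
    cfg.image_shape = (512, 512)
    cfg.boundary = BoundaryGeometry(baseline_row_um=170.0, amplitude_um=10.0, period_um=100.0)
    cfg.channels = [
        ChannelModel(
            name="bact",
            kind="punctate",
            intensity_fn=IntensityFn("constant", {"lo_um": 0.0, "hi_um": 60.0}),
            amplitude=0.5,
        )
    ]
    cfg.debris.count = 0
    cfg.seed = 9
    img, truth = generate_scene(cfg)
    pts = truth.bacterial_centroids["bact"]
    assert len(pts) > 5000
    d = compute_distance_field(truth.boundary, img.shape, img.pixel_size).values
    band_of_pixel = np.floor(d / 10.0)
    px = np.round(pts).astype(int)
    bands = band_of_pixel[px[:, 0], px[:, 1]]
    obs = np.array([(bands == b).sum() for b in range(6)])
    area = np.array([((band_of_pixel == b) & (d >= 0)).sum() for b in range(6)], dtype=float)
    expected = obs.sum() * area / area.sum()
    p = sps.chisquare(obs, expected).pvalue
    assert p > 0.01


def test_debris_disjoint_from_puncta(default_scene):
    img, truth = default_scene
    pts = np.round(truth.bacterial_centroids["EUB338"]).astype(int)
    assert not truth.debris_mask[pts[:, 0], pts[:, 1]].any()


def test_group_experiment_effect_ratio_on_peak():
    """Zero noise, no background: group-mean peak ratio equals the effect exactly."""
    cfg = make_zero_noise_config()
    cfg.channels = [
        ChannelModel(
            name="MUC2",
            kind="diffuse",
            intensity_fn=IntensityFn("gaussian_peak", {"center_um": 11.0, "sd_um": 4.0}),
            amplitude=20.0,
        )
    ]
    cfg.debris.count = 0
    records = make_group_experiment(cfg, n_per_group=5, effect=3.0, seed=7)
    peaks = {"WT": [], "R451C": []}
    for r in records:
        field = compute_distance_field(r.truth.boundary, r.image.shape, r.image.pixel_size)
        prof = bin_profile(r.image.channel("MUC2"), field, 1.0, (0, 40))
        peaks[r.group].append(np.nanmax(prof.bin_means))
    ratio = np.mean(peaks["R451C"]) / np.mean(peaks["WT"])
    assert ratio == pytest.approx(3.0, rel=1e-9)


def test_group_experiment_reproducible_and_labelled():
    cfg = make_zero_noise_config()
    recs1 = make_group_experiment(cfg, n_per_group=2, effect=2.0, seed=3)
    recs2 = make_group_experiment(cfg, n_per_group=2, effect=2.0, seed=3)
    assert [r.animal for r in recs1] == ["WT_1", "WT_2", "R451C_1", "R451C_2"]
    for a, b in zip(recs1, recs2):
        assert a.image.data.tobytes() == b.image.data.tobytes()


def test_null_effect_scales_nothing():
    cfg = make_zero_noise_config()
    cfg.debris.count = 0
    recs = make_group_experiment(cfg, n_per_group=1, effect=1.0, seed=3)
    # same generative distribution: identical channel amplitudes in both groups
    assert recs[0].truth.channel_models["MUC2"].amplitude == pytest.approx(
        recs[1].truth.channel_models["MUC2"].amplitude
    )


@pytest.mark.parametrize(
    "mutate, field",
    [
        (lambda c: setattr(c, "pixel_size", 0.0), "pixel_size"),
        (lambda c: setattr(c.debris, "count", -1), "debris.count"),
        (lambda c: setattr(c.nuclei, "radius_um", (0.0, 2.0)), "nuclei.radius_um"),
        (lambda c: setattr(c.boundary, "amplitude_um", 1e6), "boundary.amplitude_um"),
        (lambda c: setattr(c.boundary, "period_um", -1.0), "boundary.period_um"),
    ],
)
def test_invalid_config_names_offending_field(mutate, field):
    cfg = default_scene_config()
    mutate(cfg)
    with pytest.raises(ConfigurationError, match=field.split(".")[-1]):
        generate_scene(cfg)


def test_intensity_fn_negative_inside_tissue_rejected():
    with pytest.raises(ConfigurationError, match="inside tissue"):
        ChannelModel(
            name="bad",
            kind="diffuse",
            intensity_fn=IntensityFn("constant", {"lo_um": -10.0}),
            amplitude=1.0,
        ).validate()


def test_make_group_experiment_preconditions():
    cfg = make_zero_noise_config()
    with pytest.raises(ConfigurationError, match="n_per_group"):
        make_group_experiment(cfg, n_per_group=0)
    with pytest.raises(ConfigurationError, match="effect"):
        make_group_experiment(cfg, n_per_group=1, effect=0.0)
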