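"""Boundary detection, manual rasterization, orientation."""

import numpy as np
import pytest

from mucoprofiler.boundary import (
    BoundaryParams,
    boundary_mae,
    detect_boundary,
    manual_boundary,
    orient_luminal_side,
)
from mucoprofiler.errors import AmbiguityError, ConfigurationError, DetectionError
from mucoprofiler.scene import generate_scene
from tests.conftest import make_zero_noise_config


def half_plane_dapi(shape=(120, 80), r0=60, bright=100.0, noise=0.0, seed=0):
    """Tissue (bright) occupies rows >= r0."""
    img = np.zeros(shape)
    img[r0:, :] = bright
    if noise:
        img += np.random.default_rng(seed).normal(0, noise, shape)
    return img


class TestDetect:
    def test_half_plane_step_edge(self):
        r0 = 60
        b = detect_boundary(half_plane_dapi(r0=r0, noise=2.0), BoundaryParams(), pixel_size=1.0)
        rows = b.boundary_coords[:, 0]
        cols = b.boundary_coords[:, 1]
        assert set(cols.tolist()) == set(range(80))  # full width
        assert np.all(np.abs(rows - r0) <= 1)
        assert b.luminal_side == "above"
        assert b.provenance == "automatic"

    def test_chain_is_8_connected_on_mask_edge(self, default_scene):
        img, _ = default_scene
        b = detect_boundary(img.channel("DAPI"), BoundaryParams(), img.pixel_size)
        coords = b.boundary_coords
        steps = np.abs(np.diff(coords, axis=0)).max(axis=1)
        assert (steps <= 1).mean() > 0.99  # 8-connected chain (rare re-anchoring jumps allowed)
        assert b.tissue_mask[coords[:, 0], coords[:, 1]].all()
        # every boundary pixel faces the lumen
        lumen = ~b.tissue_mask
        padded = np.pad(lumen, 1, constant_values=False)
        has_lumen_neighbour = (
            padded[:-2, 1:-1] | padded[2:, 1:-1] | padded[1:-1, :-2] | padded[1:-1, 2:]
        )
        assert has_lumen_neighbour[coords[:, 0], coords[:, 1]].all()

    def test_sinusoidal_scene_accuracy(self, default_scene):
        img, truth = default_scene
        b = detect_boundary(img.channel("DAPI"), BoundaryParams(), img.pixel_size)
        assert boundary_mae(b.boundary_coords, truth.boundary_coords) <= 2.0

    def test_blank_image_errors(self):
        with pytest.raises(DetectionError, match="no tissue"):
            detect_boundary(np.zeros((64, 64)), BoundaryParams(), 1.0)

    def test_orientation_symmetry_under_flip(self):
        cfg = make_zero_noise_config()
        cfg.seed = 6
        img, _ = generate_scene(cfg)
        dapi = img.channel("DAPI")
        b = detect_boundary(dapi, BoundaryParams(), img.pixel_size)
        b_flip = detect_boundary(dapi[::-1], BoundaryParams(), img.pixel_size)
        assert {"above", "below"} == {b.luminal_side, b_flip.luminal_side}
        mirrored = {(dapi.shape[0] - 1 - r, c) for r, c in b_flip.boundary_coords}
        assert mirrored == {tuple(p) for p in b.boundary_coords}

    def test_scale_consistency_on_upsampled_image(self):
        cfg = make_zero_noise_config()
        cfg.seed = 8
        img, _ = generate_scene(cfg)
        dapi = img.channel("DAPI")
        b1 = detect_boundary(dapi, BoundaryParams(), img.pixel_size)
        up = np.kron(dapi, np.ones((2, 2)))
        b2 = detect_boundary(up, BoundaryParams(), img.pixel_size / 2)
        coarse = b2.boundary_coords / 2.0
        assert boundary_mae(coarse, b1.boundary_coords) <= 1.0

    def test_noise_robustness_monotone(self):
        errs = []
        for sd, gain in [(12.0, 4.0), (6.0, 2.0), (0.0, 0.0)]:
            per_scene = []
            for seed in (21, 22, 23):
                cfg = make_zero_noise_config()
                cfg.noise.gaussian_sd, cfg.noise.poisson_gain = sd, gain
                cfg.seed = seed
                img, truth = generate_scene(cfg)
                b = detect_boundary(img.channel("DAPI"), BoundaryParams(), img.pixel_size)
                per_scene.append(boundary_mae(b.boundary_coords, truth.boundary_coords))
            errs.append(np.mean(per_scene))
        assert errs[0] >= errs[1] - 0.05 >= errs[2] - 0.1


class TestOrient:
    def test_ambiguous_symmetric_scene(self):
        # two equally bright bands: DAPI equal on both sides of the given boundary
        dapi = np.full((60, 40), 50.0)
        from mucoprofiler.boundary import EpithelialBoundary

        coords = np.column_stack([np.full(40, 30), np.arange(40)])
        tissue = np.arange(60)[:, None] >= 30
        b = EpithelialBoundary(tissue_mask=tissue, boundary_coords=coords)
        with pytest.raises(AmbiguityError, match="ambiguous"):
            orient_luminal_side(b, dapi, pixel_size=1.0)

    def test_inverted_scene_flips_orientation(self):
        b_top = detect_boundary(half_plane_dapi(), BoundaryParams(), 1.0)
        inverted = half_plane_dapi()[::-1]
        b_bot = detect_boundary(inverted, BoundaryParams(), 1.0)
        assert b_top.luminal_side == "above"
        assert b_bot.luminal_side == "below"


class TestManual:
    def test_horizontal_polyline_rasterization(self):
        # y = 25 um at pixel_size 0.5 -> boundary at pixel row 50, lumen below
        poly = np.array([[0.0, 25.0], [49.5, 25.0]])
        b = manual_boundary(poly, (100, 100), pixel_size=0.5, luminal_side="below")
        assert b.provenance == "manual"
        assert np.all(b.boundary_coords[:, 0] == 50)
        assert b.tissue_mask[:50].all() and not b.tissue_mask[51:].any()

    def test_diagonal_polyline_8_connected(self):
        poly = np.array([[0.0, 3.0], [59.0, 47.0]])
        b = manual_boundary(poly, (60, 60), pixel_size=1.0, luminal_side="above")
        steps = np.abs(np.diff(b.boundary_coords, axis=0)).max(axis=1)
        assert np.all(steps == 1)  # no gaps, no duplicates

    def test_single_vertex_errors(self):
        with pytest.raises(ConfigurationError, match="n>=2"):
            manual_boundary(np.array([[5.0, 5.0]]), (20, 20), 1.0, "above")

    def test_self_intersecting_errors(self):
        poly = np.array([[0.0, 0.0], [19.0, 19.0], [0.0, 19.0], [19.0, 0.0]])
        with pytest.raises(ConfigurationError, match="self-intersecting"):
            manual_boundary(poly, (20, 20), 1.0, "above")

    def test_not_spanning_errors(self):
        poly = np.array([[5.0, 10.0], [8.0, 10.0]])
        with pytest.raises(ConfigurationError, match="span"):
            manual_boundary(poly, (20, 20), 1.0, "above")

    def test_vertex_outside_frame_errors(self):
        poly = np.array([[0.0, 10.0], [25.0, 10.0]])
        with pytest.raises(ConfigurationError, match="outside"):
            manual_boundary(poly, (20, 20), 1.0, "above")
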