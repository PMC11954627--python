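"""Distance field, binning, normalization, windows, peaks, aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mucoprofiler.boundary import EpithelialBoundary
from mucoprofiler.errors import ProfileError
from mucoprofiler.profiles import (
    DensityProfile,
    aggregate_by_animal,
    bin_profile,
    compute_distance_field,
    extract_window,
    find_peak,
    frame_to_profiles,
    normalize_profile,
    profiles_to_frame,
)


def straight_boundary(shape=(20, 20), col=0):
    """Vertical chain at a column; tissue is that column and everything left of it."""
    rows = np.arange(shape[0])
    coords = np.column_stack([rows, np.full_like(rows, col)])
    tissue = np.zeros(shape, dtype=bool)
    tissue[:, : col + 1] = True
    return EpithelialBoundary(tissue_mask=tissue, boundary_coords=coords, luminal_side="right")


def random_boundary(rng, shape=(32, 32)):
    """Random single-valued boundary row per column, tissue below."""
    rows = np.clip(
        (shape[0] // 2 + np.cumsum(rng.integers(-1, 2, shape[1]))), 2, shape[0] - 3
    )
    tissue = np.arange(shape[0])[:, None] >= rows[None, :]
    coords = np.column_stack([rows, np.arange(shape[1])])
    return EpithelialBoundary(tissue_mask=tissue, boundary_coords=coords, luminal_side="above")


def brute_force_field(boundary, shape, pixel_size):
    coords = boundary.boundary_coords.astype(float)
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    d = np.sqrt(((pts[:, None, :] - coords[None, :, :]) ** 2).sum(-1)).min(axis=1)
    d = d.reshape(shape) * pixel_size
    return np.where(boundary.tissue_mask, -d, d)


class TestDistanceField:
    def test_straight_boundary_closed_form(self):
        b = straight_boundary((8, 8), col=0)
        f = compute_distance_field(b, (8, 8), pixel_size=1.0)
        for c in range(8):
            assert np.all(f.values[:, c] == (c if c > 0 else 0))

    def test_sign_convention_adjacent_tissue_pixel(self):
        b = straight_boundary((8, 8), col=2)
        f = compute_distance_field(b, (8, 8), pixel_size=0.5)
        assert np.all(f.values[:, 1] == -0.5)  # one pixel inside tissue
        assert np.all(f.values[:, 2] == 0.0)   # the boundary chain itself

    def test_matches_brute_force_on_random_boundaries(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            b = random_boundary(rng)
            f = compute_distance_field(b, b.tissue_mask.shape, pixel_size=0.7)
            np.testing.assert_array_equal(
                f.values, brute_force_field(b, b.tissue_mask.shape, 0.7)
            )

    def test_empty_boundary_errors(self):
        b = EpithelialBoundary(np.zeros((4, 4), bool), np.empty((0, 2), dtype=int))
        with pytest.raises(ProfileError, match="empty"):
            compute_distance_field(b, (4, 4), 1.0)


class TestBinProfile:
    def test_uniform_channel(self):
        b = straight_boundary((16, 16))
        f = compute_distance_field(b, (16, 16), 1.0)
        p = bin_profile(np.full((16, 16), 7.0), f, bin_width=2.0, bin_range=(0, 10))
        ok = p.bin_counts > 0
        assert np.all(p.bin_means[ok] == 7.0)

    def test_matches_brute_force_group_by(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            b = random_boundary(rng)
            shape = b.tissue_mask.shape
            f = compute_distance_field(b, shape, 0.9)
            channel = rng.normal(size=shape)
            exclude = rng.random(shape) < 0.1
            p = bin_profile(channel, f, 1.3, (0, 9.1), exclude_mask=exclude)
            # oracle: per-pixel group-by
            for k in range(p.n_bins):
                lo, hi = p.bin_edges[k], p.bin_edges[k + 1]
                sel = (f.values >= lo) & (f.values < hi) & ~exclude
                if sel.sum() == 0:
                    assert np.isnan(p.bin_means[k]) and p.bin_counts[k] == 0
                else:
                    assert p.bin_counts[k] == sel.sum()
                    assert p.bin_means[k] == pytest.approx(channel[sel].mean(), abs=1e-12)

    def test_channel_equal_to_distance(self):
        b = straight_boundary((16, 16))
        f = compute_distance_field(b, (16, 16), 1.0)
        p = bin_profile(f.values.copy(), f, 1.0, (0, 10))
        ok = p.bin_counts > 0
        centers = p.bin_centers[ok]
        # column c has distance exactly c, so each occupied bin mean is an integer
        assert np.allclose(p.bin_means[ok], np.floor(centers))

    def test_errors(self):
        b = straight_boundary((8, 8))
        f = compute_distance_field(b, (8, 8), 1.0)
        ch = np.ones((8, 8))
        with pytest.raises(ProfileError, match="bin_width"):
            bin_profile(ch, f, 0.0, (0, 5))
        with pytest.raises(ProfileError, match="inside the tissue"):
            bin_profile(ch, f, 1.0, (-5, 0))
        with pytest.raises(ProfileError, match="shape"):
            bin_profile(np.ones((4, 4)), f, 1.0, (0, 5))
        with pytest.raises(ProfileError, match="empty"):
            bin_profile(ch, f, 1.0, (100, 110))


def make_profile(means, normalized=False, **kw):
    means = np.asarray(means, dtype=float)
    return DensityProfile(
        bin_edges=np.arange(len(means) + 1, dtype=float),
        bin_means=means,
        bin_counts=np.where(np.isnan(means), 0, 10).astype(np.int64),
        channel="x",
        normalized=normalized,
        **kw,
    )


class TestNormalize:
    def test_three_point_example(self):
        p = normalize_profile(make_profile([1, 2, 3]))
        np.testing.assert_allclose(p.bin_means, [-1, 0, 1])
        assert p.normalized

    def test_idempotent_on_z_scores(self):
        p = normalize_profile(make_profile([1.0, 4.0, 2.0, 8.0]))
        q = normalize_profile(p)
        np.testing.assert_allclose(q.bin_means, p.bin_means, atol=1e-12)

    def test_constant_profile_errors(self):
        with pytest.raises(ProfileError, match="constant"):
            normalize_profile(make_profile([5, 5, 5]))

    def test_single_bin_errors(self):
        with pytest.raises(ProfileError, match="2 non-missing"):
            normalize_profile(make_profile([5.0]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=3,
            max_size=60,
        )
    )
    def test_invariant_mean_zero_sd_one(self, values):
        values = np.array(values)
        if values.std(ddof=1) < 1e-9:
            return
        p = normalize_profile(make_profile(values))
        ok = ~np.isnan(p.bin_means)
        assert abs(p.bin_means[ok].mean()) < 1e-9
        assert abs(p.bin_means[ok].std(ddof=1) - 1) < 1e-9

    def test_missing_bins_stay_missing(self):
        p = normalize_profile(make_profile([1, np.nan, 2, 3]))
        assert np.isnan(p.bin_means[1])
        ok = ~np.isnan(p.bin_means)
        assert abs(p.bin_means[ok].mean()) < 1e-9


class TestWindowAndPeak:
    def test_window_counting(self):
        p = make_profile(np.arange(100.0))
        w = extract_window(p, 0, 20)
        assert w.n_bins == 20
        np.testing.assert_array_equal(w.bin_means, np.arange(20.0))

    def test_window_identity(self):
        p = make_profile(np.arange(10.0))
        w = extract_window(p, 0, 10)
        np.testing.assert_array_equal(w.bin_means, p.bin_means)

    def test_window_misaligned_errors(self):
        with pytest.raises(ProfileError, match="align"):
            extract_window(make_profile(np.arange(30.0)), 7.5, 20)

    def test_peak_monotone_decreasing(self):
        d, v = find_peak(make_profile([9, 7, 5, 1]))
        assert (d, v) == (0.5, 9)

    def test_peak_tie_breaks_toward_smaller_distance(self):
        means = np.zeros(12)
        means[5] = means[9] = 4.0
        d, _ = find_peak(make_profile(means))
        assert d == 5.5

    def test_peak_all_missing_errors(self):
        with pytest.raises(ProfileError, match="non-missing"):
            find_peak(make_profile([np.nan, np.nan]))


class TestAggregate:
    def test_single_image_identity(self):
        p = make_profile([1, 2, 3], animal="m1", group="WT")
        (agg,) = aggregate_by_animal([p])
        np.testing.assert_array_equal(agg.bin_means, p.bin_means)
        assert agg.animal == "m1" and agg.group == "WT"

    def test_duplicate_images_idempotent(self):
        p = make_profile([1, 2, 3], animal="m1", group="WT")
        (agg,) = aggregate_by_animal([p, p])
        np.testing.assert_array_equal(agg.bin_means, p.bin_means)

    def test_binwise_mean_oracle_and_missing_propagation(self):
        a = make_profile([1, 2, np.nan], animal="m1", group="WT")
        b = make_profile([3, 6, 5], animal="m1", group="WT")
        c = make_profile([10, 10, 10], animal="m2", group="KO")
        aggs = {p.animal: p for p in aggregate_by_animal([a, b, c])}
        np.testing.assert_array_equal(aggs["m1"].bin_means[:2], [2.0, 4.0])
        assert np.isnan(aggs["m1"].bin_means[2])  # missing propagates
        np.testing.assert_array_equal(aggs["m2"].bin_means, [10, 10, 10])

    def test_mixed_grids_error(self):
        a = make_profile([1, 2, 3], animal="m1")
        b = make_profile([1, 2, 3, 4], animal="m1")
        with pytest.raises(ProfileError, match="mixed bin grids"):
            aggregate_by_animal([a, b])


def test_tidy_frame_round_trip():
    p1 = make_profile([1, 2, np.nan], animal="m1", group="WT", image_id="i1")
    p2 = normalize_profile(make_profile([5, 1, 2, 9], animal="m2", group="KO", image_id="i2"))
    frame = profiles_to_frame([p1, p2])
    back = {p.image_id: p for p in frame_to_profiles(frame)}
    np.testing.assert_array_equal(back["i1"].bin_means, p1.bin_means)
    np.testing.assert_allclose(back["i2"].bin_means, p2.bin_means)
    assert back["i2"].normalized and not back["i1"].normalized
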