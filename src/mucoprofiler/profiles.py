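"""Distance-resolved fluorescence density profiles.

Given an epithelial boundary, every pixel is assigned a signed Euclidean distance to
the boundary chain (positive into the lumen, negative into the tissue, micrometres).
Channel intensity is then averaged along the epithelium into uniform distance bins,
z-normalized (mean-subtracted, divided by the standard deviation), windowed, and
summarised (peak localisation, per-animal aggregation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import ProfileError

__all__ = [
    "DistanceField",
    "DensityProfile",
    "compute_distance_field",
    "bin_profile",
    "normalize_profile",
    "extract_window",
    "find_peak",
    "aggregate_by_animal",
    "profiles_to_frame",
    "frame_to_profiles",
]


@dataclass
class DistanceField:
    """Per-pixel signed distance to the epithelial boundary, in micrometres.

    Positive on the luminal side, negative inside tissue, zero exactly on the
    boundary pixel chain.
    """

    values: np.ndarray
    pixel_size: float


def compute_distance_field(boundary, image_shape: tuple[int, int], pixel_size: float) -> DistanceField:
    """Signed Euclidean distance transform to the boundary pixel chain.

    ``|field|`` at a pixel equals the minimum Euclidean distance to any boundary
    pixel (times ``pixel_size``); the sign is negative inside ``boundary.tissue_mask``.

    Parameters
    ----------
    boundary
        Object with ``boundary_coords`` ((n, 2) row/col int array) and
        ``tissue_mask`` (bool array of ``image_shape``).
    """
    coords = np.asarray(boundary.boundary_coords)
    if coords.size == 0:
        raise ProfileError("boundary is empty")
    if not pixel_size > 0:
        raise ProfileError("pixel_size must be > 0")
    not_boundary = np.ones(image_shape, dtype=bool)
    not_boundary[coords[:, 0], coords[:, 1]] = False
    dist_px = ndi.distance_transform_edt(not_boundary)
    sign = np.where(np.asarray(boundary.tissue_mask, dtype=bool), -1.0, 1.0)
    return DistanceField(values=dist_px * pixel_size * sign, pixel_size=pixel_size)


@dataclass
class DensityProfile:
    """Mean channel intensity per distance bin.

    Bins are uniform and half-open ``[lo, hi)``; ``bin_means`` holds NaN (a true
    missing-value marker, never a silent zero) wherever ``bin_counts`` is zero.
    """

    bin_edges: np.ndarray          # length n_bins + 1, micrometres
    bin_means: np.ndarray          # length n_bins, NaN where empty
    bin_counts: np.ndarray         # pixels contributing per bin
    channel: str
    normalized: bool = False
    image_id: str = ""
    animal: str = ""
    group: str = ""
    extra: dict = field(default_factory=dict)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1


def bin_profile(
    channel: np.ndarray,
    distance_field: DistanceField,
    bin_width: float,
    bin_range: tuple[float, float] = (0.0, 100.0),
    exclude_mask: np.ndarray | None = None,
    *,
    channel_name: str = "",
    image_id: str = "",
    animal: str = "",
    group: str = "",
) -> DensityProfile:
    """Average *channel* intensity into uniform distance bins along the epithelium.

    Each pixel contributes to the bin containing its (pixel-centre) signed distance;
    pixels under *exclude_mask* (e.g. debris) are dropped from both the sum and the
    count, so masked regions never bias bin means.
    """
    lo, hi = float(bin_range[0]), float(bin_range[1])
    if not bin_width > 0:
        raise ProfileError("bin_width must be > 0")
    if not hi > lo:
        raise ProfileError("bin range must satisfy hi > lo")
    if hi <= 0:
        raise ProfileError("bin range lies entirely inside the tissue (hi <= 0)")
    channel = np.asarray(channel, dtype=float)
    d = distance_field.values
    if channel.shape != d.shape:
        raise ProfileError(f"channel shape {channel.shape} != distance field shape {d.shape}")
    if exclude_mask is not None:
        exclude_mask = np.asarray(exclude_mask, dtype=bool)
        if exclude_mask.shape != d.shape:
            raise ProfileError("exclude_mask shape mismatch")

    n_bins = int(np.ceil((hi - lo) / bin_width - 1e-9))
    edges = lo + bin_width * np.arange(n_bins + 1)
    valid = (d >= lo) & (d < edges[-1])
    if exclude_mask is not None:
        valid &= ~exclude_mask
    idx = np.floor((d[valid] - lo) / bin_width).astype(np.intp)
    counts = np.bincount(idx, minlength=n_bins).astype(np.int64)
    sums = np.bincount(idx, weights=channel[valid], minlength=n_bins)
    if counts.sum() == 0:
        raise ProfileError("all distance bins are empty")
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return DensityProfile(
        bin_edges=edges,
        bin_means=means,
        bin_counts=counts,
        channel=channel_name,
        normalized=False,
        image_id=image_id,
        animal=animal,
        group=group,
    )


def normalize_profile(profile: DensityProfile) -> DensityProfile:
    """z-normalize: subtract the mean and divide by the sample SD of the bin means.

    Missing bins are excluded from the statistics and stay missing. The sample
    (n-1) standard deviation is used; a constant or single-bin profile is an error.
    """
    values = profile.bin_means
    ok = ~np.isnan(values)
    if ok.sum() < 2:
        raise ProfileError("need at least 2 non-missing bins to normalize")
    mean = values[ok].mean()
    sd = values[ok].std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ProfileError("profile is constant (SD = 0); cannot normalize")
    return replace(profile, bin_means=(values - mean) / sd, normalized=True)


def extract_window(profile: DensityProfile, lo: float, hi: float) -> DensityProfile:
    """Return the sub-profile on ``[lo, hi)``; the window must align with bin edges."""
    edges = profile.bin_edges
    tol = 1e-9
    i_lo = np.argmin(np.abs(edges - lo))
    i_hi = np.argmin(np.abs(edges - hi))
    if abs(edges[i_lo] - lo) > tol or abs(edges[i_hi] - hi) > tol:
        raise ProfileError(f"window [{lo}, {hi}) does not align with the bin grid")
    if i_hi <= i_lo:
        raise ProfileError(f"window [{lo}, {hi}) is empty")
    return replace(
        profile,
        bin_edges=edges[i_lo : i_hi + 1].copy(),
        bin_means=profile.bin_means[i_lo:i_hi].copy(),
        bin_counts=profile.bin_counts[i_lo:i_hi].copy(),
    )


def find_peak(profile: DensityProfile) -> tuple[float, float]:
    """Locate the profile maximum.

    Returns ``(peak_distance, peak_value)`` where the distance is the centre of the
    argmax bin; ties break toward the smaller distance.
    """
    values = profile.bin_means
    if np.all(np.isnan(values)):
        raise ProfileError("profile has no non-missing bins")
    k = int(np.nanargmax(values))  # first occurrence -> smaller distance on ties
    return float(profile.bin_centers[k]), float(values[k])


def _same_grid(a: DensityProfile, b: DensityProfile) -> bool:
    return a.bin_edges.shape == b.bin_edges.shape and np.allclose(a.bin_edges, b.bin_edges)


def aggregate_by_animal(profiles: Sequence[DensityProfile]) -> list[DensityProfile]:
    """Bin-wise mean of each animal's image profiles (one output profile per animal).

    All inputs must share the bin grid and channel; a bin missing in any of an
    animal's images is missing in the aggregate. Pixel counts are summed.
    """
    if not profiles:
        raise ProfileError("no profiles to aggregate")
    ref = profiles[0]
    for p in profiles[1:]:
        if not _same_grid(ref, p):
            raise ProfileError("profiles use mixed bin grids")
        if p.channel != ref.channel:
            raise ProfileError("profiles mix channels; aggregate one channel at a time")
        if not p.animal:
            raise ProfileError("every profile needs an animal label")
    out: list[DensityProfile] = []
    for animal in sorted({p.animal for p in profiles}):
        mine = [p for p in profiles if p.animal == animal]
        groups = {p.group for p in mine}
        if len(groups) != 1:
            raise ProfileError(f"animal {animal!r} carries conflicting group labels {groups}")
        stack = np.vstack([p.bin_means for p in mine])
        out.append(
            DensityProfile(
                bin_edges=ref.bin_edges.copy(),
                bin_means=stack.mean(axis=0),  # plain mean: missing bins propagate
                bin_counts=np.vstack([p.bin_counts for p in mine]).sum(axis=0),
                channel=ref.channel,
                normalized=mine[0].normalized,
                image_id="",
                animal=animal,
                group=groups.pop(),
            )
        )
    return out


def profiles_to_frame(profiles: Iterable[DensityProfile]) -> pd.DataFrame:
    """Tidy long-form table: one row per (profile, bin)."""
    rows = []
    for p in profiles:
        for k in range(p.n_bins):
            rows.append(
                {
                    "image": p.image_id,
                    "animal": p.animal,
                    "group": p.group,
                    "channel": p.channel,
                    "bin_lo_um": p.bin_edges[k],
                    "bin_hi_um": p.bin_edges[k + 1],
                    "mean": p.bin_means[k],
                    "n_pixels": int(p.bin_counts[k]),
                    "normalized": bool(p.normalized),
                }
            )
    return pd.DataFrame(rows)


def frame_to_profiles(frame: pd.DataFrame) -> list[DensityProfile]:
    """Rebuild :class:`DensityProfile` objects from a tidy table (inverse of
    :func:`profiles_to_frame`)."""
    out = []
    keys = ["image", "animal", "group", "channel", "normalized"]
    for vals, sub in frame.groupby(keys, sort=True, dropna=False):
        sub = sub.sort_values("bin_lo_um")
        edges = np.append(sub["bin_lo_um"].to_numpy(), sub["bin_hi_um"].iloc[-1])
        out.append(
            DensityProfile(
                bin_edges=edges,
                bin_means=sub["mean"].to_numpy(dtype=float),
                bin_counts=sub["n_pixels"].to_numpy(dtype=np.int64),
                channel=str(vals[3]),
                normalized=bool(vals[4]),
                image_id=str(vals[0]),
                animal=str(vals[1]),
                group=str(vals[2]),
            )
        )
    return out
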