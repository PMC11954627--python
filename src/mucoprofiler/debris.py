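"""Autofluorescent debris identification and subtraction.

Luminal objects (plant material, shed epithelial cells) fluoresce across spectrally
distinct channels and would otherwise be counted as microbial or mucus signal.
Objects are segmented on the luminal side of the boundary, classified as debris by
three auditable rules — broadband fluorescence, oversize, or DAPI-positive luminal
tissue fragment — and subtracted (set to the background estimate) from the signal
channels before profiling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import ConfigurationError, ProfileError
from .image import MultichannelImage

__all__ = [
    "DebrisParams",
    "DebrisMask",
    "segment_luminal_objects",
    "classify_debris",
    "subtract_debris",
    "evaluate_debris_detection",
]


@dataclass
class DebrisParams:
    """Debris classification thresholds.

    ``broadband_ratio`` is the minimum ratio of the second-brightest to brightest
    (threshold-normalised) channel intensity for an object to count as broadband;
    areas are in square micrometres.
    """

    broadband_ratio: float = 0.5
    size_max_bacterium: float = 20.0   # um^2; larger luminal objects are debris candidates
    min_object_area: float = 0.5       # um^2; smaller components are discarded as noise
    noise_floor_sigma: float = 4.0     # per-channel threshold floor above luminal background

    def __post_init__(self) -> None:
        if not (0 < self.broadband_ratio <= 1):
            raise ConfigurationError("broadband_ratio: must be in (0, 1]")
        if not (self.size_max_bacterium > self.min_object_area > 0):
            raise ConfigurationError(
                "areas: need size_max_bacterium > min_object_area > 0"
            )


@dataclass
class DebrisMask:
    """Binary debris mask plus the per-object audit table.

    The table has one row per segmented luminal object: label, area (um^2),
    per-channel mean intensity, the debris call and its reason
    (``broadband`` | ``oversize`` | ``luminal-tissue-fragment`` | ``""``).
    """

    mask: np.ndarray
    objects: pd.DataFrame
    labels: np.ndarray


def _channel_thresholds(
    image: MultichannelImage, names: Sequence[str], luminal: np.ndarray, floor_sigma: float
) -> dict[str, float]:
    """Per-channel object threshold over luminal pixels: Otsu, floored at
    background mean + ``floor_sigma`` * SD so pure-noise channels yield ~no objects."""
    from skimage.filters import threshold_otsu

    out = {}
    for name in names:
        vals = image.channel(name)[luminal]
        floor = float(vals.mean() + floor_sigma * vals.std())
        try:
            otsu = float(threshold_otsu(vals))
        except ValueError:  # constant channel
            otsu = np.inf
        out[name] = max(otsu, floor)
    return out


def segment_luminal_objects(
    image: MultichannelImage,
    tissue_mask: np.ndarray,
    params: DebrisParams | None = None,
    channel_names: Sequence[str] | None = None,
) -> tuple[np.ndarray, dict[str, float]]:
    """Segment supra-threshold objects on the luminal side.

    Connected components (8-connectivity) of the union of per-channel supra-
    threshold masks, restricted to non-tissue pixels; components below
    ``min_object_area`` are discarded. Returns the labelled object map and the
    per-channel thresholds used (needed by :func:`classify_debris`).

    *channel_names* selects the channels driving segmentation; diffuse channels
    (e.g. the mucus stain) should normally be excluded, otherwise the whole mucus
    band segments as one object. Intensities of all channels are still measured
    during classification.
    """
    params = params or DebrisParams()
    if channel_names is None:
        channel_names = list(image.channels)
    if len(channel_names) < 2:
        raise ConfigurationError("segmentation needs >= 2 channels (one signal + DAPI)")
    luminal = ~np.asarray(tissue_mask, dtype=bool)
    if not luminal.any():
        raise ProfileError("no luminal pixels: tissue mask covers the frame")

    thresholds = _channel_thresholds(image, channel_names, luminal, params.noise_floor_sigma)
    supra = np.zeros(image.shape, dtype=bool)
    for name in channel_names:
        supra |= image.channel(name) > thresholds[name]
    supra &= luminal
    labels, _ = ndi.label(supra, structure=np.ones((3, 3), dtype=bool))
    min_px = max(1, int(round(params.min_object_area / image.pixel_size**2)))
    sizes = np.bincount(labels.ravel())
    too_small = np.flatnonzero(sizes < min_px)
    labels[np.isin(labels, too_small[too_small > 0])] = 0
    return labels, thresholds


def classify_debris(
    labels: np.ndarray,
    image: MultichannelImage,
    thresholds: dict[str, float],
    params: DebrisParams | None = None,
    dapi_channel: str = "DAPI",
) -> DebrisMask:
    """Classify each segmented luminal object as debris or microbial signal.

    An object is debris iff any of:

    - **broadband**: threshold-normalised mean intensity > 1 in at least two
      spectrally distinct channels, with second-brightest/brightest ratio
      >= ``broadband_ratio`` (autofluorescence is flat across channels, FISH and
      mucus signals are not);
    - **oversize**: area > ``size_max_bacterium``;
    - **luminal-tissue-fragment**: DAPI-positive while disconnected from the
      tissue (shed epithelial cells carry nuclei, bacteria show no DAPI at
      tissue-imaging settings).
    """
    params = params or DebrisParams()
    if not image.has_channel(dapi_channel):
        raise ConfigurationError(
            f"channel set lacks {dapi_channel!r}: luminal-tissue-fragment rule undecidable"
        )
    labels = np.asarray(labels)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    px_area = image.pixel_size**2

    meas_channels = [c for c in image.channels]
    means = {
        c: ndi.mean(image.channel(c), labels=labels, index=ids) if len(ids) else np.empty(0)
        for c in meas_channels
    }
    areas = (
        ndi.sum_labels(np.ones_like(labels, dtype=float), labels=labels, index=ids) * px_area
        if len(ids)
        else np.empty(0)
    )

    rows = []
    debris_ids = []
    for k, obj in enumerate(ids):
        norm = {
            c: means[c][k] / thresholds[c]
            for c in meas_channels
            if c in thresholds and thresholds[c] > 0
        }
        supra = sorted((v for v in norm.values() if v > 1), reverse=True)
        broadband = len(supra) >= 2 and (supra[1] / supra[0]) >= params.broadband_ratio
        oversize = areas[k] > params.size_max_bacterium
        fragment = norm.get(dapi_channel, 0.0) > 1
        reason = (
            "broadband"
            if broadband
            else "oversize" if oversize else "luminal-tissue-fragment" if fragment else ""
        )
        if reason:
            debris_ids.append(obj)
        row = {"label": int(obj), "area_um2": float(areas[k]), "debris": bool(reason), "reason": reason}
        row.update({f"mean_{c}": float(means[c][k]) for c in meas_channels})
        rows.append(row)

    table = pd.DataFrame(
        rows,
        columns=["label", "area_um2", "debris", "reason"] + [f"mean_{c}" for c in meas_channels],
    )
    mask = np.isin(labels, np.asarray(debris_ids, dtype=labels.dtype))
    return DebrisMask(mask=mask, objects=table, labels=labels)


def subtract_debris(channel: np.ndarray, mask: DebrisMask | np.ndarray, background: float = 0.0) -> np.ndarray:
    """Replace pixels under the debris mask with the background estimate.

    Idempotent; every off-mask pixel is returned unchanged (exactly).
    """
    m = mask.mask if isinstance(mask, DebrisMask) else np.asarray(mask, dtype=bool)
    channel = np.asarray(channel, dtype=float)
    if m.shape != channel.shape:
        raise ProfileError(f"mask shape {m.shape} != channel shape {channel.shape}")
    out = channel.copy()
    out[m] = background
    return out


def evaluate_debris_detection(
    predicted_mask: np.ndarray, true_mask: np.ndarray, min_overlap: float = 0.3
) -> tuple[float, float]:
    """Object-level precision and recall of a debris mask against ground truth.

    A predicted object is a true positive when at least ``min_overlap`` of its
    area lies on the true mask; a true object counts as recovered when at least
    ``min_overlap`` of it is covered by the prediction.
    """
    struct = np.ones((3, 3), dtype=bool)
    pred_labels, n_pred = ndi.label(np.asarray(predicted_mask, dtype=bool), structure=struct)
    true_labels, n_true = ndi.label(np.asarray(true_mask, dtype=bool), structure=struct)
    if n_pred == 0:
        return (1.0 if n_true == 0 else 0.0), (1.0 if n_true == 0 else 0.0)
    pred_ids = np.arange(1, n_pred + 1)
    true_ids = np.arange(1, n_true + 1)
    overlap_frac_pred = ndi.mean(np.asarray(true_mask, dtype=float), pred_labels, pred_ids)
    precision = float((overlap_frac_pred >= min_overlap).mean())
    if n_true == 0:
        return precision, 1.0
    overlap_frac_true = ndi.mean(np.asarray(predicted_mask, dtype=float), true_labels, true_ids)
    recall = float((overlap_frac_true >= min_overlap).mean())
    return precision, recall
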