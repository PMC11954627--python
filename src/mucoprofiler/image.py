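"""Calibrated multichannel image container and TIFF I/O.

Images are stored channel-first (C, H, W) as float arrays with named channels and a
micrometre pixel calibration. Files are written as multipage TIFF with the channel
names and pixel size embedded in the (JSON) shaped metadata so a round trip
preserves identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

from .errors import ConfigurationError

__all__ = ["MultichannelImage", "read_image", "write_image"]


@dataclass
class MultichannelImage:
    """A 2-D fluorescence image with named channels and a physical pixel size.

    Parameters
    ----------
    data
        Array of shape (n_channels, height, width), intensity in arbitrary units.
    channels
        One name per channel, e.g. ``("DAPI", "MUC2", "EUB338")``.
    pixel_size
        Lateral calibration in micrometres per pixel (> 0).
    metadata
        Free-form per-image metadata (image id, animal id, group label, ...).
    """

    data: np.ndarray
    channels: tuple[str, ...]
    pixel_size: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.channels = tuple(self.channels)
        if self.data.ndim != 3:
            raise ConfigurationError("data: expected a (channels, rows, cols) array")
        if len(self.channels) != self.data.shape[0]:
            raise ConfigurationError(
                f"channels: {len(self.channels)} names for {self.data.shape[0]} planes"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ConfigurationError("channels: names must be unique")
        if not self.pixel_size > 0:
            raise ConfigurationError("pixel_size: must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of each channel plane."""
        return self.data.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        """Return the 2-D plane for channel *name*."""
        try:
            return self.data[self.channels.index(name)]
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channels}") from None

    def has_channel(self, name: str) -> bool:
        return name in self.channels


def write_image(path, image: MultichannelImage) -> None:
    """Write *image* as a float32 multipage TIFF with channel/pixel-size metadata."""
    meta = {
        "axes": "CYX",
        "channels": list(image.channels),
        "pixel_size_um": float(image.pixel_size),
        "image_metadata": {k: v for k, v in image.metadata.items()},
    }
    tifffile.imwrite(path, image.data.astype(np.float32), photometric="minisblack", metadata=meta)


def read_image(path) -> MultichannelImage:
    """Read a TIFF written by :func:`write_image` back into a :class:`MultichannelImage`."""
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        shaped = tf.shaped_metadata
        meta = dict(shaped[0]) if shaped else {}
    if data.ndim == 2:
        data = data[None]
    channels = tuple(meta.get("channels", [f"ch{i}" for i in range(data.shape[0])]))
    pixel_size = float(meta.get("pixel_size_um", 1.0))
    extra = dict(meta.get("image_metadata", {}))
    return MultichannelImage(data=data, channels=channels, pixel_size=pixel_size, metadata=extra)
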