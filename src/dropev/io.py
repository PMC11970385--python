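"""Image container and multi-page TIFF plumbing.

A frame is a set of co-registered 2-D channel images (brightfield plus
fluorescence channels) sharing one pixel grid and a physical pixel size.
Frames are stored on disk as multi-page TIFF, one page per channel, with
the channel order and pixel size recorded in the TIFF description.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile

#: Canonical channel order used when writing multi-page TIFF.
DEFAULT_CHANNEL_ORDER = ("brightfield", "DAPI", "Cy5", "FITC")


@dataclass
class ImageFrame:
    """Multi-channel field of view.

    Parameters
    ----------
    channels
        Mapping of channel name to 2-D intensity array. All channels must
        share the same shape.
    pixel_size_um
        Physical size of one pixel in micrometres; must be positive.
    frame_id
        Identifier carried through to per-droplet tables.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    frame_id: str = "frame0"

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        shapes = {name: ch.shape for name, ch in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(
                f"channel {name!r} not present; available: {sorted(self.channels)}"
            )
        return self.channels[name]


def save_frame_tiff(frame: ImageFrame, path: str | Path,
                    channel_order: tuple[str, ...] | None = None) -> None:
    """Write a frame as a 16-bit multi-page TIFF (one page per channel)."""
    order = tuple(channel_order or [c for c in DEFAULT_CHANNEL_ORDER
                                    if c in frame.channels])
    missing = set(frame.channels) - set(order)
    if missing:
        order = order + tuple(sorted(missing))
    meta = {"channels": list(order),
            "pixel_size_um": frame.pixel_size_um,
            "frame_id": frame.frame_id}
    pages = np.stack([np.clip(frame.channels[c], 0, 65535).astype(np.uint16)
                      for c in order])
    tifffile.imwrite(path, pages, description=json.dumps(meta))


def load_frame_tiff(path: str | Path,
                    channel_order: tuple[str, ...] | None = None,
                    pixel_size_um: float | None = None) -> ImageFrame:
    """Read a multi-page TIFF frame.

    Channel names and pixel size are taken from the embedded JSON
    description when present; otherwise ``channel_order`` and
    ``pixel_size_um`` must be supplied.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        desc = tif.pages[0].description
    if pages.ndim == 2:
        pages = pages[None]
    meta: Mapping = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    order = channel_order or meta.get("channels")
    if order is None:
        raise ValueError(
            f"{path}: no channel metadata in TIFF and no channel_order given")
    if len(order) != pages.shape[0]:
        raise ValueError(
            f"{path}: {pages.shape[0]} pages but {len(order)} channel names")
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    if px is None:
        raise ValueError(f"{path}: pixel size not in metadata and not given")
    frame_id = meta.get("frame_id", path.stem)
    channels = {name: pages[i].astype(np.float64) for i, name in enumerate(order)}
    return ImageFrame(channels=channels, pixel_size_um=float(px), frame_id=frame_id)
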