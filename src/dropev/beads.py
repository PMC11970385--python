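"""Bead detection in coding channels (DAPI / Cy5) and droplet assignment.

Beads are bright diffraction-limited spots. Detection follows the
"find maxima" idiom: the channel is lightly smoothed, the flat
background (global median) subtracted, and local maxima above an
intensity threshold with a minimum pairwise separation are kept. The
default threshold is 5 robust noise SDs, estimated by the median
absolute deviation, which keeps the per-droplet false-detection rate
well below 1e-3 on Gaussian backgrounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max

from .io import ImageFrame
from .segmentation import DropletSegmentation

__all__ = ["BeadDetection", "detect_beads", "assign_beads", "beads_to_frame"]

BEAD_CHANNELS = ("DAPI", "Cy5")

_MAD_TO_SD = 1.4826


@dataclass
class BeadDetection:
    """One detected bead: channel, pixel position, peak intensity."""

    channel: str
    row_px: int
    col_px: int
    intensity: float
    droplet_label: int | None = None  # filled by assign_beads


def detect_beads(frame: ImageFrame, channel: str,
                 intensity_threshold: float | None = None,
                 min_separation_px: int = 3,
                 smooth_sigma: float = 1.0) -> list[BeadDetection]:
    """Detect bead spots in one coding channel.

    Parameters
    ----------
    channel
        ``"DAPI"`` or ``"Cy5"``.
    intensity_threshold
        Absolute prominence above the local (flat) background, in the
        smoothed image. ``None`` uses 5 robust noise SDs.
    min_separation_px
        Minimum pairwise distance between detections; the brighter peak
        wins within that radius.
    """
    if channel not in BEAD_CHANNELS:
        raise ValueError(
            f"unknown bead channel {channel!r}; expected one of {BEAD_CHANNELS}")
    img = frame.channel(channel).astype(np.float64)
    if smooth_sigma > 0:
        img = ndi.gaussian_filter(img, smooth_sigma)
    img = img - np.median(img)
    if intensity_threshold is None:
        noise_sd = _MAD_TO_SD * np.median(np.abs(img - np.median(img)))
        intensity_threshold = 5.0 * noise_sd
    if intensity_threshold <= 0:
        raise ValueError("intensity_threshold must be > 0")
    peaks = peak_local_max(img, min_distance=int(min_separation_px),
                           threshold_abs=float(intensity_threshold))
    return [BeadDetection(channel=channel, row_px=int(r), col_px=int(c),
                          intensity=float(img[r, c]))
            for r, c in peaks]


def assign_beads(beads: list[BeadDetection],
                 seg: DropletSegmentation) -> DropletSegmentation:
    """Assign detections to the droplet whose footprint contains them.

    Updates per-droplet per-color bead counts in ``seg.table`` in place
    (a copy of the table is stored back) and records the droplet label
    on each detection. Beads falling outside every droplet stay
    unassigned; they are counted, not fatal.
    """
    table = seg.table.copy()
    counts = {ch: dict.fromkeys(table["label"], 0) for ch in BEAD_CHANNELS}
    n_unassigned = 0
    for b in beads:
        lab = int(seg.labels[b.row_px, b.col_px])
        if lab > 0 and lab in counts[b.channel]:
            counts[b.channel][lab] += 1
            b.droplet_label = lab
        else:
            b.droplet_label = None
            n_unassigned += 1
    table["n_beads_dapi"] = table["label"].map(counts["DAPI"]).astype(int)
    table["n_beads_cy5"] = table["label"].map(counts["Cy5"]).astype(int)
    table.attrs["n_unassigned_beads"] = n_unassigned
    seg.table = table
    return seg


def beads_to_frame(beads: list[BeadDetection],
                   pixel_size_um: float) -> pd.DataFrame:
    """Detections as a table (channel, x/y in px and um, intensity, label)."""
    return pd.DataFrame({
        "channel": [b.channel for b in beads],
        "row_px": [b.row_px for b in beads],
        "col_px": [b.col_px for b in beads],
        "x_um": [b.col_px * pixel_size_um for b in beads],
        "y_um": [b.row_px * pixel_size_um for b in beads],
        "intensity": [b.intensity for b in beads],
        "droplet_label": [b.droplet_label for b in beads],
    })
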