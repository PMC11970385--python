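"""End-to-end quantification: frames -> droplet tables -> % EV+ beads -> EV fractions.

``quantify_frames`` runs segmentation, bead detection/assignment,
background correction (with a pooled fallback for frames lacking
beadless droplets), SNR-threshold positive calling, and per-color
tallies, then converts the readout to % of EVs positive for the target
through the occupancy model.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .beads import BEAD_CHANNELS, assign_beads, detect_beads
from .calling import AssayCounts, background_correct, call_positive, tally
from .config import RunConfig
from .digital import OccupancySpec, beads_to_ev_percent
from .io import ImageFrame
from .segmentation import DropletSegmentation, segment_droplets

__all__ = ["process_frame", "quantify_frames"]


def process_frame(frame: ImageFrame, cfg: RunConfig | None = None
                  ) -> DropletSegmentation:
    """Segment one frame and assign detected beads to droplets."""
    cfg = cfg or RunConfig()
    seg = segment_droplets(frame, cfg.min_diameter_um, cfg.max_diameter_um)
    beads = []
    for ch in BEAD_CHANNELS:
        if ch in frame.channels:
            beads.extend(detect_beads(
                frame, ch,
                intensity_threshold=cfg.bead_intensity_threshold,
                min_separation_px=cfg.bead_min_separation_px))
    assign_beads(beads, seg)
    return seg


def quantify_frames(frames: Iterable[ImageFrame],
                    cfg: RunConfig | None = None) -> dict:
    """Full readout over a set of fields of view.

    Returns a dict with per-color :class:`AssayCounts` (as dicts), the
    occupancy-converted % of EVs positive for each color's target, and
    the per-frame droplet tables under ``"tables"``.
    """
    cfg = cfg or RunConfig()
    tables = [process_frame(f, cfg).table for f in frames]
    if not tables:
        raise ValueError("no frames to quantify")

    # per-frame background; frames without beadless droplets fall back
    # to the pooled estimate over all frames
    beadless = pd.concat(
        [t.loc[(t["n_beads_dapi"] + t["n_beads_cy5"]) == 0, "fitc_mean_raw"]
         for t in tables])
    pooled = (float(beadless.mean()), float(beadless.std(ddof=1))) \
        if len(beadless) > 1 else None
    called = []
    for t in tables:
        corrected = background_correct(t, pooled_background=pooled)
        called.append(call_positive(corrected, snr_threshold=cfg.snr_threshold))

    spec = OccupancySpec(ev_to_bead_ratio=cfg.ev_to_bead_ratio,
                         model=cfg.occupancy_model)
    results: dict = {"tables": called, "occupancy": {
        "model": spec.model, "ev_to_bead_ratio": spec.ev_to_bead_ratio,
        "f_occ": spec.f_occ}}
    for color in BEAD_CHANNELS:
        try:
            counts = tally(called, color)
        except ValueError:
            continue  # no beads of this color in the whole set
        entry = counts.to_dict()
        entry["ev_positive_percent"] = beads_to_ev_percent(
            counts.f_pos_percent, spec)
        results[color] = entry
    return results
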