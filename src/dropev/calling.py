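"""Positive-droplet calling and % EV+ bead tallies.

A droplet is called positive when its background-corrected mean FITC
intensity exceeds ``snr_threshold`` noise SDs AND it contains at least
one bead. The background is the mean FITC intensity of beadless
droplets (they received no enzyme, so they report pure substrate
background); its SD is the noise estimate. Fluorescent droplets without
a colocalized bead are excluded from every tally.

The assay readout is, per bead color,

    f_pos (%) = 100 * (positive droplets containing >=1 bead of that
                color) / (total beads of that color),

summed over all acquired fields of view (20 in the standard protocol).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AssayCounts", "background_correct", "call_positive", "tally"]

_COLOR_COL = {"DAPI": "n_beads_dapi", "Cy5": "n_beads_cy5"}


@dataclass
class AssayCounts:
    """Per-bead-color tally over a set of frames."""

    bead_color: str
    n_beads: int
    n_positive_droplets: int
    n_frames: int
    f_pos_percent: float
    background_mean: float = float("nan")
    background_sd: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "bead_color": self.bead_color,
            "n_beads": self.n_beads,
            "n_positive_droplets": self.n_positive_droplets,
            "n_frames": self.n_frames,
            "f_pos_percent": self.f_pos_percent,
            "background_mean": self.background_mean,
            "background_sd": self.background_sd,
        }


def _bead_count(table: pd.DataFrame) -> pd.Series:
    return table["n_beads_dapi"] + table["n_beads_cy5"]


def background_correct(table: pd.DataFrame,
                       pooled_background: tuple[float, float] | None = None
                       ) -> pd.DataFrame:
    """Subtract the beadless-droplet background from droplet intensities.

    Background mean and SD are estimated from the mean FITC intensities
    of droplets containing no bead; ``fitc_mean_corrected = raw - mean``
    is stored per droplet, and the estimates are kept in
    ``table.attrs["background_mean"/"background_sd"]``.

    Parameters
    ----------
    pooled_background
        Optional (mean, sd) from a pooled estimate across frames, used
        when this frame has no beadless droplet.

    Raises
    ------
    ValueError
        If there is no beadless droplet and no pooled fallback; the
        message points at the pooled-background option.
    """
    out = table.copy()
    beadless = out.loc[_bead_count(out) == 0, "fitc_mean_raw"]
    if len(beadless) > 0:
        mu = float(beadless.mean())
        sd = float(beadless.std(ddof=1)) if len(beadless) > 1 else 0.0
    elif pooled_background is not None:
        mu, sd = map(float, pooled_background)
    else:
        raise ValueError(
            "no beadless droplets to estimate background from; pass "
            "pooled_background=(mean, sd) computed over the frame set")
    out["fitc_mean_corrected"] = out["fitc_mean_raw"] - mu
    out.attrs["background_mean"] = mu
    out.attrs["background_sd"] = sd
    return out


def call_positive(table: pd.DataFrame,
                  snr_threshold: float = 3.0) -> pd.DataFrame:
    """Call positives at a strict SNR threshold with colocalization gating.

    positive  := corrected / sigma_bg > snr_threshold AND >=1 bead
    excluded  := corrected / sigma_bg > snr_threshold AND no bead
                 (fluorescence without a bead cannot come from the
                 assay; such droplets leave every numerator and
                 denominator)

    Requires :func:`background_correct` to have run; raises if the
    noise estimate is degenerate (sigma_bg == 0).
    """
    if "background_sd" not in table.attrs:
        raise ValueError("run background_correct before call_positive")
    sd = table.attrs["background_sd"]
    if sd == 0:
        raise ValueError("degenerate noise estimate: background SD is 0")
    out = table.copy()
    snr = out["fitc_mean_corrected"] / sd
    has_bead = _bead_count(out) >= 1
    bright = snr > snr_threshold
    out["positive"] = bright & has_bead
    out["excluded"] = bright & ~has_bead
    out.attrs.update(table.attrs)
    return out


def tally(tables: pd.DataFrame | list[pd.DataFrame],
          bead_color: str) -> AssayCounts:
    """Tally % EV+ beads for one bead color over one or more frames.

    The numerator counts positive droplets containing >=1 bead of the
    color; the denominator counts every bead of the color individually
    (a droplet holding two beads contributes two). Excluded droplets
    contribute to neither.
    """
    if bead_color not in _COLOR_COL:
        raise ValueError(f"unknown bead color {bead_color!r}")
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    col = _COLOR_COL[bead_color]
    n_beads = 0
    n_pos = 0
    bgs = []
    for t in tables:
        ok = ~t["excluded"]
        n_beads += int(t.loc[ok, col].sum())
        n_pos += int((t.loc[ok, "positive"] & (t.loc[ok, col] >= 1)).sum())
        if "background_mean" in t.attrs:
            bgs.append((t.attrs["background_mean"], t.attrs["background_sd"]))
    if n_beads == 0:
        raise ValueError(f"zero {bead_color} beads: % EV+ beads is undefined")
    bg_mean = float(np.mean([b[0] for b in bgs])) if bgs else float("nan")
    bg_sd = float(np.mean([b[1] for b in bgs])) if bgs else float("nan")
    return AssayCounts(
        bead_color=bead_color,
        n_beads=n_beads,
        n_positive_droplets=n_pos,
        n_frames=len(tables),
        f_pos_percent=100.0 * n_pos / n_beads,
        background_mean=bg_mean,
        background_sd=bg_sd,
    )
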