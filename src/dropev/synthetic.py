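"""Ground-truthed synthetic data: droplet-array frames and cohort tables.

The generator emulates the statistical structure of a droplet-confined
digital immunoassay for single extracellular vesicles (EVs):

* a packed monolayer of monodisperse water-in-oil droplets (~27.9 um
  diameter, ~2,500-3,500 per 953x1432 um^2 field of view),
* Poisson loading of antibody-coated capture beads into droplets
  (lambda ~ 0.1, so ~90% of droplets are empty),
* two fluorescent bead color codes (DAPI-coded and Cy5-coded) for
  multiplexing,
* Poisson capture of target EVs onto beads at a bead:EV excess of ~10:1,
  so occupied beads almost always carry a single EV,
* enzymatic FITC signal filling droplets whose bead carries at least one
  detected EV, over additive Gaussian background noise.

Every frame is returned together with its exact :class:`GroundTruth`, so
segmentation, bead detection and positive calling can be scored against
known answers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import ImageFrame

__all__ = [
    "FrameConfig",
    "GroundTruth",
    "CohortConfig",
    "GroupSpec",
    "generate_frame",
    "generate_cohort",
    "PackingError",
]

# Rendering constants (16-bit ADU). Brightfield: bright oil background
# and inter-droplet films, dark droplet body with darker rim;
# fluorescence channels: dim baseline.
_BF_BACKGROUND = 30000.0
_BF_INTERIOR = 0.35 * _BF_BACKGROUND
_BF_RIM = 0.22 * _BF_BACKGROUND
_FLUOR_BASELINE = 500.0


class PackingError(RuntimeError):
    """Requested droplet count cannot be placed in the frame."""


@dataclass
class FrameConfig:
    """Parameters of one synthetic field of view.

    Geometry defaults match the assay's imaging format: a 953x1432 um^2
    field holding a packed monolayer of ~27.9 um droplets.

    Parameters
    ----------
    frame_width_um, frame_height_um
        Physical field size in micrometres.
    pixel_size_um
        Micrometres per pixel. 0.65 corresponds to a 10x objective on a
        standard sCMOS camera.
    droplet_diameter_mean_um, droplet_diameter_cv
        Droplet size model (normal, truncated at +-3 CV).
    placement
        ``"hex"`` — jittered hexagonal lattice emulating the squeezed
        monolayer (default); ``"dart"`` — random sequential addition with
        a minimum center distance of one mean diameter, for sparse frames
        with fully circular, non-overlapping footprints.
    spacing_factor
        Hex mode: lattice spacing as a fraction of the mean diameter.
        0.85 yields ~2,800 droplets per default frame.
    n_droplets
        Dart mode: number of droplets to place. Ignored in hex mode.
    bead_lambda
        Mean beads per droplet (Poisson). Default 0.104 reproduces the
        working loading regime (90.1% empty droplets, ~9.4% singles).
    bead_color_mix
        Probability that a bead is DAPI-coded (vs Cy5-coded).
    ev_lambda_per_bead
        Mean target EVs captured per bead (Poisson). Either one rate for
        all beads or a mapping ``{"DAPI": r1, "Cy5": r2}`` for duplex
        targets. Default 0.1 = the 10:1 bead:EV excess.
    p_positive_given_ev
        Probability that a bead carrying >=1 EV produces FITC signal
        (detection efficiency of the enzymatic readout).
    snr_true
        FITC fill amplitude of a positive droplet in units of pixel
        noise SD.
    bead_snr
        Peak amplitude of a bead spot in its coding channel, in units of
        pixel noise SD.
    noise_sd
        Additive Gaussian noise SD (ADU) on all fluorescence channels.
    seed
        Random seed; identical config + seed gives identical output.
    """

    frame_width_um: float = 1432.0
    frame_height_um: float = 953.0
    pixel_size_um: float = 0.65
    droplet_diameter_mean_um: float = 27.9
    droplet_diameter_cv: float = 0.03
    placement: str = "hex"
    spacing_factor: float = 0.85
    n_droplets: int | None = None
    bead_lambda: float = 0.104
    bead_color_mix: float = 0.5
    ev_lambda_per_bead: float | Mapping[str, float] = 0.1
    p_positive_given_ev: float = 1.0
    snr_true: float = 10.0
    bead_snr: float = 10.0
    bead_diameter_um: float = 3.0
    noise_sd: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.droplet_diameter_mean_um <= 0:
            raise ValueError("droplet_diameter_mean_um must be > 0")
        for name in ("bead_lambda", "noise_sd", "snr_true", "bead_snr",
                     "droplet_diameter_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("bead_color_mix", "p_positive_given_ev"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        rates = (self.ev_lambda_per_bead.values()
                 if isinstance(self.ev_lambda_per_bead, Mapping)
                 else [self.ev_lambda_per_bead])
        if any(r < 0 for r in rates):
            raise ValueError("ev_lambda_per_bead must be >= 0")
        if self.placement not in ("hex", "dart"):
            raise ValueError(f"placement must be 'hex' or 'dart', got {self.placement!r}")

    def ev_rate(self, color: str) -> float:
        if isinstance(self.ev_lambda_per_bead, Mapping):
            return float(self.ev_lambda_per_bead[color])
        return float(self.ev_lambda_per_bead)


@dataclass
class GroundTruth:
    """Exact per-droplet and per-bead record of a synthetic frame.

    ``droplets`` columns: droplet_id, x_um, y_um, diameter_um,
    n_beads_dapi, n_beads_cy5, n_ev, true_positive.
    ``beads`` columns: bead_id, droplet_id, channel, x_um, y_um, n_ev,
    positive.
    ``totals``: frame-level tallies derived from the tables (droplet
    count, beads per color, true positive droplets per color, true
    % EV+ beads per color).
    """

    droplets: pd.DataFrame
    beads: pd.DataFrame
    totals: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "droplets": self.droplets.to_dict(orient="list"),
            "beads": self.beads.to_dict(orient="list"),
            "totals": self.totals,
        }


def _place_hex(cfg: FrameConfig, rng: np.random.Generator) -> np.ndarray:
    """Jittered hexagonal lattice of droplet centers (um), squeezed-monolayer emulation."""
    s = cfg.spacing_factor * cfg.droplet_diameter_mean_um
    row_pitch = s * math.sqrt(3.0) / 2.0
    margin = 0.5 * cfg.droplet_diameter_mean_um * 0.6
    ys = np.arange(margin, cfg.frame_height_um - margin, row_pitch)
    centers = []
    jitter = 0.04 * s
    for i, y in enumerate(ys):
        x0 = margin + (0.5 * s if i % 2 else 0.0)
        xs = np.arange(x0, cfg.frame_width_um - margin, s)
        pts = np.column_stack([xs, np.full_like(xs, y)])
        centers.append(pts)
    pts = np.concatenate(centers)
    pts += rng.uniform(-jitter, jitter, size=pts.shape)
    return pts


def _place_dart(cfg: FrameConfig, rng: np.random.Generator) -> np.ndarray:
    """Random sequential addition with min center distance = mean diameter."""
    n = cfg.n_droplets
    if n is None:
        raise ValueError("dart placement requires n_droplets")
    d = cfg.droplet_diameter_mean_um
    margin = 0.5 * d
    lo = np.array([margin, margin])
    hi = np.array([cfg.frame_width_um - margin, cfg.frame_height_um - margin])
    if np.any(hi <= lo):
        raise PackingError("frame too small for a single droplet")
    placed: list[np.ndarray] = []
    # grid-accelerated rejection sampling
    cell = d
    grid: dict[tuple[int, int], list[int]] = {}
    max_attempts = 200 * n
    attempts = 0
    while len(placed) < n and attempts < max_attempts:
        attempts += 1
        p = rng.uniform(lo, hi)
        ci, cj = int(p[0] // cell), int(p[1] // cell)
        ok = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for k in grid.get((ci + di, cj + dj), ()):
                    if np.sum((placed[k] - p) ** 2) < d * d:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            grid.setdefault((ci, cj), []).append(len(placed))
            placed.append(p)
    if len(placed) < n:
        raise PackingError(
            f"could not place {n} droplets; achieved {len(placed)} "
            f"after {attempts} attempts")
    return np.asarray(placed)


def generate_frame(cfg: FrameConfig) -> tuple[ImageFrame, GroundTruth]:
    """Render one synthetic field of view with exact ground truth.

    Returns a 4-channel frame (brightfield, DAPI, Cy5, FITC) and the
    matching :class:`GroundTruth`. Deterministic for a fixed config.

    Raises
    ------
    PackingError
        In dart mode, when the requested droplet count cannot be placed;
        the message names the achieved count.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.placement == "hex":
        centers = _place_hex(cfg, rng)
    else:
        centers = _place_dart(cfg, rng)
    n_drop = len(centers)

    d_mean, cv = cfg.droplet_diameter_mean_um, cfg.droplet_diameter_cv
    diam = rng.normal(d_mean, cv * d_mean, size=n_drop)
    diam = np.clip(diam, d_mean * (1 - 3 * cv), d_mean * (1 + 3 * cv))

    # --- bead loading: Poisson per droplet, Bernoulli color code
    n_beads = rng.poisson(cfg.bead_lambda, size=n_drop)
    bead_rows = []
    drop_dapi = np.zeros(n_drop, dtype=int)
    drop_cy5 = np.zeros(n_drop, dtype=int)
    drop_nev = np.zeros(n_drop, dtype=int)
    drop_pos = np.zeros(n_drop, dtype=bool)
    bead_id = 0
    for i in range(n_drop):
        placed_xy: list[tuple[float, float]] = []
        for _ in range(n_beads[i]):
            color = "DAPI" if rng.random() < cfg.bead_color_mix else "Cy5"
            n_ev = rng.poisson(cfg.ev_rate(color))
            pos = bool(n_ev >= 1 and rng.random() < cfg.p_positive_given_ev)
            # bead sits inside the droplet, away from the rim; beads are
            # hard spheres and cannot interpenetrate
            for _attempt in range(50):
                rr = 0.5 * diam[i] * 0.55 * math.sqrt(rng.random())
                th = rng.uniform(0, 2 * math.pi)
                bx = centers[i, 0] + rr * math.cos(th)
                by = centers[i, 1] + rr * math.sin(th)
                if all((bx - qx) ** 2 + (by - qy) ** 2
                       >= cfg.bead_diameter_um ** 2
                       for qx, qy in placed_xy):
                    break
            placed_xy.append((bx, by))
            bead_rows.append((bead_id, i, color, bx, by, n_ev, pos))
            bead_id += 1
            if color == "DAPI":
                drop_dapi[i] += 1
            else:
                drop_cy5[i] += 1
            drop_nev[i] += n_ev
            drop_pos[i] |= pos

    droplets = pd.DataFrame({
        "droplet_id": np.arange(n_drop),
        "x_um": centers[:, 0],
        "y_um": centers[:, 1],
        "diameter_um": diam,
        "n_beads_dapi": drop_dapi,
        "n_beads_cy5": drop_cy5,
        "n_ev": drop_nev,
        "true_positive": drop_pos,
    })
    beads = pd.DataFrame(
        bead_rows,
        columns=["bead_id", "droplet_id", "channel", "x_um", "y_um",
                 "n_ev", "positive"],
    )

    totals: dict = {"n_droplets": int(n_drop)}
    for color, col in (("DAPI", "n_beads_dapi"), ("Cy5", "n_beads_cy5")):
        nb = int(droplets[col].sum())
        npos = int(((droplets[col] >= 1) & droplets["true_positive"]).sum())
        totals[f"n_beads_{color.lower()}"] = nb
        totals[f"n_positive_droplets_{color.lower()}"] = npos
        totals[f"f_pos_true_{color.lower()}_percent"] = (
            100.0 * npos / nb if nb else float("nan"))

    # --- rendering
    # Droplets are rendered as dark bodies clipped to their own
    # territory (nearest-center cells), separated by thin bright oil
    # films, as in a squeezed monolayer. Isolated droplets (dart mode)
    # reduce to plain dark disks with a darker rim.
    px = cfg.pixel_size_um
    shape = (int(round(cfg.frame_height_um / px)),
             int(round(cfg.frame_width_um / px)))
    bf = np.full(shape, _BF_BACKGROUND)
    fitc = np.full(shape, _FLUOR_BASELINE)
    dapi = np.full(shape, _FLUOR_BASELINE)
    cy5 = np.full(shape, _FLUOR_BASELINE)

    if n_drop == 0:
        for img in (fitc, dapi, cy5):
            img += rng.normal(0.0, cfg.noise_sd, size=shape)
        frame = ImageFrame(
            channels={"brightfield": bf, "DAPI": dapi, "Cy5": cy5,
                      "FITC": fitc},
            pixel_size_um=px, frame_id=f"synthetic-seed{cfg.seed}")
        return frame, GroundTruth(droplets=droplets, beads=beads,
                                  totals=totals)

    from scipy.spatial import cKDTree

    yy, xx = np.meshgrid(np.arange(shape[0]) * px,
                         np.arange(shape[1]) * px, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    tree = cKDTree(centers)
    k = min(2, n_drop)
    dd, ii = tree.query(pts, k=k)
    if k == 1:
        d1 = dd.ravel()
        idx = ii.ravel()
        gap = np.full_like(d1, np.inf)
    else:
        d1, idx = dd[:, 0], ii[:, 0]
        gap = dd[:, 1] - dd[:, 0]  # 0 on the midline between two droplets

    film_um = max(1.5 * px, 1.0)      # bright oil film between droplets
                                      # (>= 1.5 px so it stays resolved)
    rim_w_um = max(1.3, 1.3 * px)     # dark rim thickness
    r_own = 0.5 * diam[idx]
    body = (d1 <= r_own) & (gap > film_um)
    rim = body & ((d1 > r_own - rim_w_um) | (gap <= film_um + 2 * rim_w_um))
    bf_flat = bf.ravel()
    bf_flat[body] = _BF_INTERIOR
    bf_flat[rim] = _BF_RIM
    bf = bf_flat.reshape(shape)

    # FITC fill: uniform over the droplet body, kept off the walls so
    # a positive droplet never bleeds into its neighbours' territories
    pos_ids = np.flatnonzero(drop_pos)
    if len(pos_ids):
        fill = (np.isin(idx, pos_ids) & (d1 <= 0.9 * r_own)
                & (gap > film_um + rim_w_um))
        fitc_flat = fitc.ravel()
        fitc_flat[fill] += cfg.snr_true * cfg.noise_sd
        fitc = fitc_flat.reshape(shape)

    # bead spots: 2-D Gaussian, sigma 1.5 px
    sigma = 1.5
    half = 5
    for _, b in beads.iterrows():
        img = dapi if b["channel"] == "DAPI" else cy5
        cy_px, cx_px = b["y_um"] / px, b["x_um"] / px
        y0 = int(round(cy_px)) - half
        x0 = int(round(cx_px)) - half
        ys = np.arange(max(0, y0), min(shape[0], y0 + 2 * half + 1))
        xs = np.arange(max(0, x0), min(shape[1], x0 + 2 * half + 1))
        if len(ys) == 0 or len(xs) == 0:
            continue
        g = np.exp(-((ys[:, None] - cy_px) ** 2 + (xs[None, :] - cx_px) ** 2)
                   / (2 * sigma ** 2))
        img[np.ix_(ys, xs)] += cfg.bead_snr * cfg.noise_sd * g

    if cfg.noise_sd > 0:
        for img in (fitc, dapi, cy5):
            img += rng.normal(0.0, cfg.noise_sd, size=shape)
        bf += rng.normal(0.0, 0.3 * cfg.noise_sd, size=shape)

    frame = ImageFrame(
        channels={"brightfield": bf, "DAPI": dapi, "Cy5": cy5, "FITC": fitc},
        pixel_size_um=px,
        frame_id=f"synthetic-seed{cfg.seed}",
    )
    return frame, GroundTruth(droplets=droplets, beads=beads, totals=totals)


# ---------------------------------------------------------------------------
# cohort generation


@dataclass
class GroupSpec:
    """Marginal distribution of one subject group.

    Locations/scales are medians and interquartile ranges of the two
    assay readouts (% EV+ beads), matched by the log-normal or gamma
    sampler.
    """

    n: int
    target_median: float
    target_iqr: float
    cd81_median: float
    cd81_iqr: float

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"group size must be > 0, got {self.n}")
        for f in ("target_median", "target_iqr", "cd81_median", "cd81_iqr"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be > 0")


def _default_groups() -> dict[str, GroupSpec]:
    # Patterned on the cohort's published group summaries: alpha-synuclein
    # and CD81 % EV+ beads, median (IQR), for HC / iRBD / PD (n=20 each).
    return {
        "HC": GroupSpec(20, 1.98, 1.16, 7.50, 1.55),
        "iRBD": GroupSpec(20, 3.72, 1.29, 7.65, 1.85),
        "PD": GroupSpec(20, 3.85, 0.75, 6.87, 1.41),
    }


@dataclass
class CohortConfig:
    """Synthetic cohort: per-group medians/IQRs and a noise family."""

    groups: dict[str, GroupSpec] = field(default_factory=_default_groups)
    noise_model: str = "lognormal"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group required")
        if self.noise_model not in ("lognormal", "gamma"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


_Z75 = 0.6744897501960817  # 75th percentile of the standard normal


def _lognormal_params(median: float, iqr: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given median and IQR."""
    mu = math.log(median)

    def f(s: float) -> float:
        return median * (math.exp(_Z75 * s) - math.exp(-_Z75 * s)) - iqr

    sigma = brentq(f, 1e-9, 20.0)
    return mu, sigma


def _gamma_params(median: float, iqr: float) -> tuple[float, float]:
    """(shape, scale) of a gamma with the given median and IQR."""
    from scipy.stats import gamma as gamma_dist

    def f(log_k: float) -> float:
        k = math.exp(log_k)
        q25, q50, q75 = gamma_dist.ppf([0.25, 0.5, 0.75], k)
        return (q75 - q25) / q50 - iqr / median

    log_k = brentq(f, math.log(1e-3), math.log(1e6))
    k = math.exp(log_k)
    scale = median / gamma_dist.ppf(0.5, k)
    return k, scale


def generate_cohort(cfg: CohortConfig) -> pd.DataFrame:
    """Draw a synthetic subject table.

    Columns: subject_id, group, target_pos_percent, cd81_pos_percent,
    ratio. Readouts are drawn independently per subject from the group's
    distribution; the ratio column is target/CD81.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    sid = 0
    for name, spec in cfg.groups.items():
        if cfg.noise_model == "lognormal":
            mu_t, s_t = _lognormal_params(spec.target_median, spec.target_iqr)
            mu_c, s_c = _lognormal_params(spec.cd81_median, spec.cd81_iqr)
            target = rng.lognormal(mu_t, s_t, size=spec.n)
            cd81 = rng.lognormal(mu_c, s_c, size=spec.n)
        else:
            k_t, th_t = _gamma_params(spec.target_median, spec.target_iqr)
            k_c, th_c = _gamma_params(spec.cd81_median, spec.cd81_iqr)
            target = rng.gamma(k_t, th_t, size=spec.n)
            cd81 = rng.gamma(k_c, th_c, size=spec.n)
        for t, c in zip(target, cd81):
            rows.append((f"S{sid:04d}", name, t, c, t / c))
            sid += 1
    return pd.DataFrame(
        rows,
        columns=["subject_id", "group", "target_pos_percent",
                 "cd81_pos_percent", "ratio"],
    )
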