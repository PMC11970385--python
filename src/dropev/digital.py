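"""Digital-assay statistics: Poisson loading, occupancy conversion,
EV concentrations, and calibration with LOD/LOQ.

The assay encapsulates antibody-coated beads and EVs in picoliter
droplets. Bead loading follows Poisson statistics with mean
``lambda = concentration x droplet volume``; at the working
concentration ~90% of droplets are empty and multi-bead droplets are
rare. EVs are captured onto beads at a deliberate ~10:1 bead:EV excess
so that an occupied bead almost always carries a single EV, which makes
the readout digital: the fraction of EVs positive for a target is the
fraction of positive beads divided by the fraction of beads expected to
carry an EV at all (the occupancy fraction f_occ).

Two occupancy models are provided:

* ``ratio`` (default): f_occ = r / (1 + r) for a bead:EV loading ratio
  1:r — every EV ends up on some bead, beads compete for them. At
  r = 0.1 this gives f_occ = 1/11, i.e. % EV+ beads x 11 = % of EVs
  positive for the target.
* ``poisson``: EVs per bead ~ Poisson(r), f_occ = 1 - exp(-r).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "LoadingModel", "OccupancySpec", "CalibrationCurve",
    "poisson_loading", "single_ev_statistics", "beads_to_ev_percent",
    "ev_concentration", "fit_calibration",
]

_UM3_PER_PL = 1e3        # 1 pL = 1e3 um^3
_PL_PER_ML = 1e9         # 1 mL = 1e9 pL


@dataclass
class LoadingModel:
    """Poisson bead-loading model for spherical droplets."""

    bead_concentration_per_ml: float
    droplet_diameter_um: float
    droplet_volume_pl: float
    lambda_bead: float

    def pmf(self, k: int | np.ndarray) -> np.ndarray:
        return stats.poisson.pmf(k, self.lambda_bead)

    @property
    def p_empty(self) -> float:
        return float(self.pmf(0))

    @property
    def p_single(self) -> float:
        return float(self.pmf(1))

    @property
    def p_multi(self) -> float:
        return float(1.0 - self.pmf(0) - self.pmf(1))


def poisson_loading(bead_concentration_per_ml: float,
                    droplet_diameter_um: float) -> LoadingModel:
    """Build the loading model from a bead concentration and droplet size.

    lambda = concentration x (pi/6) d^3. Raises on negative
    concentration or non-positive diameter.
    """
    if bead_concentration_per_ml < 0:
        raise ValueError("bead concentration must be >= 0")
    if droplet_diameter_um <= 0:
        raise ValueError("droplet diameter must be > 0")
    vol_um3 = math.pi / 6.0 * droplet_diameter_um ** 3
    vol_pl = vol_um3 / _UM3_PER_PL
    lam = bead_concentration_per_ml * vol_pl / _PL_PER_ML
    return LoadingModel(bead_concentration_per_ml, droplet_diameter_um,
                        vol_pl, lam)


@dataclass
class OccupancySpec:
    """EV-per-bead occupancy: loading ratio r and model family."""

    ev_to_bead_ratio: float = 0.1
    model: str = "ratio"

    def __post_init__(self) -> None:
        if self.ev_to_bead_ratio < 0:
            raise ValueError("ev_to_bead_ratio must be >= 0")
        if self.model not in ("ratio", "poisson"):
            raise ValueError(f"model must be 'ratio' or 'poisson', got {self.model!r}")

    @property
    def f_occ(self) -> float:
        """Fraction of beads carrying at least one EV."""
        r = self.ev_to_bead_ratio
        if self.model == "ratio":
            return r / (1.0 + r)
        return 1.0 - math.exp(-r)


def single_ev_statistics(spec: OccupancySpec) -> dict:
    """Occupancy report: how digital is the readout at this loading?

    Under the Poisson model returns P(exactly 1 EV | >=1 EV) =
    r e^-r / (1 - e^-r) and its complement P(>=2 | >=1); under the ratio
    model only f_occ is defined.
    """
    r = spec.ev_to_bead_ratio
    report = {"model": spec.model, "ev_to_bead_ratio": r, "f_occ": spec.f_occ}
    if spec.model == "poisson":
        if r == 0:
            p1 = 1.0  # limit r -> 0
        else:
            p1 = r * math.exp(-r) / (1.0 - math.exp(-r))
        report["p_single_given_occupied"] = p1
        report["p_multi_given_occupied"] = 1.0 - p1
    return report


def beads_to_ev_percent(f_pos_percent: float, spec: OccupancySpec) -> float:
    """Convert % EV+ beads to % of EVs positive for the target.

    % target+ EVs = f_pos / f_occ. With the default ratio model at
    r = 0.1 (f_occ = 1/11) this is f_pos x 11. Values of f_pos above
    100 x f_occ (conversion above 100%) trigger a warning, not an error.
    """
    f_occ = spec.f_occ
    if f_occ == 0:
        raise ValueError("occupancy fraction is 0: conversion undefined")
    if not 0 <= f_pos_percent:
        raise ValueError("f_pos_percent must be >= 0")
    if f_pos_percent > 100.0 * f_occ:
        warnings.warn(
            f"f_pos={f_pos_percent}% exceeds 100 x f_occ = {100 * f_occ:.3f}%:"
            " converted value exceeds 100% of EVs", stacklevel=2)
    return f_pos_percent / f_occ


def ev_concentration(n_positive_beads: float,
                     sample_volume_ul: float,
                     dilution_factor: float = 1.0,
                     beads_assayed: float = 1.0,
                     beads_imaged: float = 1.0) -> float:
    """Target+ EVs per uL of original biofluid.

    Each positive bead reports one captured EV (single-EV regime). The
    imaged positive-bead count is scaled up by beads_assayed /
    beads_imaged (only a subset of beads lands in the acquired fields of
    view), divided by the assayed sample volume, and multiplied by the
    dilution factor.
    """
    if sample_volume_ul <= 0:
        raise ValueError("sample volume must be > 0")
    if beads_imaged <= 0 or beads_assayed <= 0:
        raise ValueError("bead counts must be > 0")
    if n_positive_beads < 0 or dilution_factor <= 0:
        raise ValueError("counts must be >= 0 and dilution factor > 0")
    return (n_positive_beads * (beads_assayed / beads_imaged)
            * dilution_factor / sample_volume_ul)


@dataclass
class CalibrationCurve:
    """Linear (or log-log) calibration with 3-sigma/10-sigma limits.

    LOD and LOQ are the concentrations whose fitted response equals the
    background mean plus 3 and 10 background SDs respectively; the
    dynamic range runs from the LOD to the highest calibrator.
    """

    concentrations: np.ndarray
    responses: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    background_mean: float
    background_sd: float
    lod: float
    loq: float
    dynamic_range: tuple[float, float]
    log_log: bool = False

    def predict(self, concentration: np.ndarray) -> np.ndarray:
        c = np.asarray(concentration, dtype=float)
        if self.log_log:
            return 10 ** (self.intercept + self.slope * np.log10(c))
        return self.intercept + self.slope * c

    def inverse(self, response: float) -> float:
        if self.log_log:
            return float(10 ** ((math.log10(response) - self.intercept)
                                / self.slope))
        return float((response - self.intercept) / self.slope)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope, "intercept": self.intercept,
            "r_squared": self.r_squared,
            "background_mean": self.background_mean,
            "background_sd": self.background_sd,
            "lod": self.lod, "loq": self.loq,
            "dynamic_range": list(self.dynamic_range),
            "log_log": self.log_log,
        }


def fit_calibration(concentrations, responses, background_replicates,
                    log_log: bool = False) -> CalibrationCurve:
    """Least-squares calibration fit with LOD/LOQ.

    Parameters
    ----------
    concentrations, responses
        >=3 calibrator points (concentration in EVs/uL, response in
        % EV+ beads).
    background_replicates
        >=2 blank responses; their mean + 3 SD / + 10 SD define the LOD
        and LOQ thresholds in response space, mapped through the inverse
        fit.
    log_log
        Fit log10(response) against log10(concentration) instead of the
        linear scales.

    Raises
    ------
    ValueError
        On too few points/replicates or a non-positive fitted slope
        (degenerate, non-monotone calibration).
    """
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    bg = np.asarray(background_replicates, dtype=float)
    if conc.shape != resp.shape or conc.ndim != 1:
        raise ValueError("concentrations and responses must be 1-D and equal length")
    if len(conc) < 3:
        raise ValueError("need >= 3 calibration points")
    if len(bg) < 2:
        raise ValueError("need >= 2 background replicates")

    if log_log:
        if np.any(conc <= 0) or np.any(resp <= 0):
            raise ValueError("log-log fit requires positive concentrations and responses")
        fit = stats.linregress(np.log10(conc), np.log10(resp))
    else:
        fit = stats.linregress(conc, resp)
    if fit.slope <= 0:
        raise ValueError(
            f"degenerate calibration: fitted slope {fit.slope:.4g} <= 0")

    mu_bg = float(bg.mean())
    sd_bg = float(bg.std(ddof=1))
    if sd_bg == 0:
        warnings.warn("background SD is 0: LOD and LOQ collapse to the "
                      "blank response", stacklevel=2)

    curve = CalibrationCurve(
        concentrations=conc, responses=resp,
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
        background_mean=mu_bg, background_sd=sd_bg,
        lod=float("nan"), loq=float("nan"),
        dynamic_range=(float("nan"), float("nan")),
        log_log=log_log,
    )
    curve.lod = curve.inverse(mu_bg + 3.0 * sd_bg)
    curve.loq = curve.inverse(mu_bg + 10.0 * sd_bg)
    curve.dynamic_range = (curve.lod, float(conc.max()))
    return curve
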