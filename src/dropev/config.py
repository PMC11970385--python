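"""Run configuration: YAML schema, validation, provenance."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Configuration schema violation; the message names the field path."""


@dataclass
class RunConfig:
    """Settings tying the pipeline together.

    Defaults reproduce the assay's standard protocol: positives called
    at SNR > 3, twenty fields of view per measurement, and a 10:1
    bead:EV loading excess (r = 0.1, ratio occupancy model).
    """

    frames_dir: str | None = None
    output_dir: str = "dropev_out"
    channel_map: dict[str, int] = field(default_factory=lambda: {
        "brightfield": 0, "DAPI": 1, "Cy5": 2, "FITC": 3})
    min_diameter_um: float | None = None
    max_diameter_um: float | None = None
    bead_intensity_threshold: float | None = None
    bead_min_separation_px: int = 3
    snr_threshold: float = 3.0
    ev_to_bead_ratio: float = 0.1
    occupancy_model: str = "ratio"
    n_fields_of_view: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr_threshold <= 0:
            raise ConfigError(
                f"snr_threshold: must be > 0, got {self.snr_threshold}")
        if self.ev_to_bead_ratio < 0:
            raise ConfigError(
                f"ev_to_bead_ratio: must be >= 0, got {self.ev_to_bead_ratio}")
        if self.occupancy_model not in ("ratio", "poisson"):
            raise ConfigError(
                f"occupancy_model: must be 'ratio' or 'poisson', "
                f"got {self.occupancy_model!r}")
        if self.n_fields_of_view <= 0:
            raise ConfigError(
                f"n_fields_of_view: must be > 0, got {self.n_fields_of_view}")
        if self.bead_min_separation_px < 1:
            raise ConfigError(
                f"bead_min_separation_px: must be >= 1, "
                f"got {self.bead_min_separation_px}")
        if (self.min_diameter_um is not None and self.max_diameter_um is not None
                and not self.min_diameter_um < self.max_diameter_um):
            raise ConfigError(
                "min_diameter_um/max_diameter_um: need min < max, got "
                f"[{self.min_diameter_um}, {self.max_diameter_um}]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(
                f"{path}: unknown field(s) {sorted(unknown)}; "
                f"known fields: {sorted(known)}")
        try:
            return cls(**raw)
        except TypeError as e:
            raise ConfigError(f"{path}: {e}") from e

    def to_dict(self) -> dict:
        return asdict(self)

    def provenance(self) -> dict:
        """Config hash + seed, attached to every output artifact."""
        from . import __version__
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return {
            "config_sha256": hashlib.sha256(blob).hexdigest(),
            "seed": self.seed,
            "dropev_version": __version__,
        }
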