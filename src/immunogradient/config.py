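"""Run configuration: a single YAML file validated before any stage runs.

The full configuration is echoed into every output for provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(Exception):
    """Invalid or inconsistent run configuration (CLI exit code 1)."""


class DataError(Exception):
    """Unreadable or inconsistent input data (CLI exit code 2)."""


@dataclass
class SlideInput:
    """Paths for one slide: a mask raster (or GeoJSON) plus a cell table."""

    slide: str
    mask: str
    cells: str


@dataclass
class RunConfig:
    # geometry
    pixel_size_um: float = 0.5
    band_width_um: float = 10.0
    max_width_um: float = 150.0
    min_boundary_um: float = 1000.0
    variant_widths_um: tuple[float, ...] = tuple(range(20, 301, 10))
    label_codes: dict | None = None
    # statistics
    alpha: float = 0.05
    cv_folds: int = 5
    n_train: int = 117
    n_test: int = 40
    horizon_months: float = 60.0
    # randomness and paths
    seed: int = 0
    output_dir: str = "results"
    slides: list[SlideInput] = field(default_factory=list)
    clinical: str | None = None
    # synthetic generation (optional section, passed through to the generators)
    generate: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.band_width_um <= 0:
            raise ConfigError("pixel_size_um and band_width_um must be positive")
        ratio = self.max_width_um / self.band_width_um
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigError("max_width_um must be a multiple of band_width_um")
        if self.min_boundary_um < 0:
            raise ConfigError("min_boundary_um must be >= 0")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")
        for w in self.variant_widths_um:
            r = w / self.band_width_um
            if abs(r - round(r)) > 1e-9:
                raise ConfigError(f"variant width {w} is not a multiple of the band width")

    @property
    def grid_max_width_um(self) -> float:
        """Zone width the band map must reach to serve the variant grid."""
        return max(self.max_width_um, max(self.variant_widths_um, default=0.0))

    def echo(self) -> dict:
        """Plain-dict provenance copy of the configuration."""
        d = dataclasses.asdict(self)
        d["variant_widths_um"] = list(self.variant_widths_um)
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        slides = [SlideInput(**s) for s in raw.pop("slides", [])]
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "variant_widths_um" in raw:
            raw["variant_widths_um"] = tuple(raw["variant_widths_um"])
        return cls(slides=slides, **raw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except OSError as err:
            raise ConfigError(f"cannot read config {path}: {err}") from err
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(raw)

    def ensure_output_dir(self) -> Path:
        p = Path(self.output_dir)
        p.mkdir(parents=True, exist_ok=True)
        return p
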