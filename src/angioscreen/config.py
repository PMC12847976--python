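"""Pipeline configuration: nested YAML with strict (unknown-key) validation."""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .types import ParameterError


class ConfigError(ParameterError):
    """Malformed configuration."""


@dataclass
class GeometryConfig:
    rows: int = 1024
    cols: int = 1024
    center_row: float = 512.0
    center_col: float = 512.0
    radius: float = 300.0
    pixel_size_um: Optional[float] = None


@dataclass
class PreprocessConfig:
    rolling_ball_radius: float = 50.0
    smooth_sigma: float = 0.0


@dataclass
class SegmentationConfig:
    backend: str = "otsu"
    thick_width_px: float = 4.0
    min_object_px: int = 50
    spur_prune_px: float = 3.0


@dataclass
class StatisticsConfig:
    control_label: str = "DMSO"
    adjust: str = "bh"  # bh | bonferroni
    design: str = "auto"  # auto | parametric | nonparametric
    exclude_chips: list[str] = field(default_factory=list)


@dataclass
class PipelineConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    statistics: StatisticsConfig = field(default_factory=StatisticsConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        s = self.segmentation
        for name, v in (
            ("rolling_ball_radius", self.preprocess.rolling_ball_radius),
            ("thick_width_px", s.thick_width_px),
            ("min_object_px", s.min_object_px),
            ("geometry radius", self.geometry.radius),
        ):
            if v <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.statistics.adjust not in ("bh", "bonferroni"):
            raise ConfigError("statistics.adjust must be 'bh' or 'bonferroni'")
        if self.statistics.design not in ("auto", "parametric", "nonparametric"):
            raise ConfigError("statistics.design must be auto|parametric|nonparametric")

    def chip_geometry(self):
        from .types import ChipGeometry

        g = self.geometry
        return ChipGeometry(
            shape=(g.rows, g.cols),
            center=(g.center_row, g.center_col),
            radius=g.radius,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path) -> None:
        """Echo the effective (defaults-resolved) config next to outputs."""
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


_SECTIONS = {
    "geometry": GeometryConfig,
    "preprocess": PreprocessConfig,
    "segmentation": SegmentationConfig,
    "statistics": StatisticsConfig,
}


def _build(cls, data: dict, where: str):
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")
    return cls(**data)


def load_config(path=None, overrides: Optional[dict] = None) -> PipelineConfig:
    """Load a YAML config file; unknown keys are rejected, not ignored."""
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
        data = raw
    if overrides:
        for key, sub in overrides.items():
            data.setdefault(key, {})
            if isinstance(sub, dict):
                data[key].update(sub)
            else:
                data[key] = sub

    unknown = set(data) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = data.get(name, {})
        if not isinstance(section, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        kwargs[name] = _build(cls, section, name)
    return PipelineConfig(seed=int(data.get("seed", 0)), **kwargs)
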