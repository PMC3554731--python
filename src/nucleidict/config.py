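"""Run configuration: every tunable of the pipeline in one YAML-round-trippable object."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .detection import DetectionConfig
from .dictionary import DiskDictionary, build_dictionary
from .errors import ConfigurationError
from .preprocessing import PreprocessConfig
from .segmentation import EnergyParams

__all__ = ["DictionarySpec", "RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class DictionarySpec:
    """Radius interval of the disk dictionary, in pixels or micrometres.

    With ``units = "um"`` the radii are divided by the per-image pixel
    size before the dictionary is built, so physical size priors (e.g. a
    nucleus diameter interval measured on the microscope) carry over
    between magnifications.
    """

    r_min: float = 10.0
    r_max: float = 10.0
    step: float = 1.0
    units: str = "px"

    def __post_init__(self) -> None:
        if self.units not in ("px", "um"):
            raise ConfigurationError(f"dictionary units must be 'px' or 'um', got {self.units!r}")

    def build(self, pixel_size_um: float) -> DiskDictionary:
        scale = 1.0 if self.units == "px" else 1.0 / pixel_size_um
        return build_dictionary(self.r_min * scale, self.r_max * scale, self.step * scale)


@dataclass(frozen=True)
class RunConfig:
    """Effective configuration of a detection / evaluation run."""

    preprocess: PreprocessConfig | None = None  # None: norm_radius derived from dictionary
    energy: EnergyParams = field(default_factory=EnergyParams)
    dictionary: DictionarySpec = field(default_factory=DictionarySpec)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    match_radius_um: float = 3.2
    pixel_size_um: float = 1.0
    output_dir: str = "."
    log_level: str = "INFO"

    def build_dictionary(self) -> DiskDictionary:
        return self.dictionary.build(self.pixel_size_um)

    def resolved_preprocess(self, dic: DiskDictionary) -> PreprocessConfig:
        """Preprocess config with norm_radius defaulted to 4 x the largest atom radius."""
        if self.preprocess is not None:
            return self.preprocess
        return PreprocessConfig(norm_radius=int(round(4 * dic.r_max)))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("preprocess") is not None:
            d["preprocess"] = PreprocessConfig(**d["preprocess"])
        if "energy" in d:
            d["energy"] = EnergyParams(**d["energy"])
        if "dictionary" in d:
            d["dictionary"] = DictionarySpec(**d["dictionary"])
        if "detection" in d:
            d["detection"] = DetectionConfig(**d["detection"])
        return cls(**d)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
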