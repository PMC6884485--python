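"""Layered pipeline configuration: built-in defaults < YAML file < CLI flags.

The built-in defaults are the published analysis settings (0.5 µm working
pixel, 8 µm background radius, 1.5 µm sigma, nucleus area in [10, 400] µm²,
OD threshold 0.1, background cap 2 OD; smoothing radii 25 and 50 µm; an
8-hidden-layer MLP capped at 100 iterations; eTIL% threshold 16.6).  Every
block is validated against its module's invariants before any computation
starts, so an invalid configuration never touches an image.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from etilscore.detection import DetectionParams

__all__ = ["PipelineConfig", "ClassifierConfig", "ScoringConfig", "CutpointConfig"]


@dataclass
class ClassifierConfig:
    hidden_width: int = 32
    max_iter: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.hidden_width < 1:
            raise ValueError("classifier.hidden_width must be >= 1")
        if self.max_iter < 1:
            raise ValueError("classifier.max_iter must be >= 1")


@dataclass
class ScoringConfig:
    threshold: float = 16.6
    high_is_strictly_greater: bool = True

    def validate(self) -> None:
        if not 0 <= self.threshold <= 100:
            raise ValueError("scoring.threshold must lie in [0, 100]")


@dataclass
class CutpointConfig:
    min_group_fraction: float = 0.1
    n_splits: int = 100
    train_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.min_group_fraction < 0.5:
            raise ValueError("cutpoint.min_group_fraction must lie in (0, 0.5)")
        if not 0 < self.train_fraction < 1:
            raise ValueError("cutpoint.train_fraction must lie in (0, 1)")
        if self.n_splits < 1:
            raise ValueError("cutpoint.n_splits must be >= 1")


@dataclass
class PipelineConfig:
    detection: DetectionParams = field(default_factory=DetectionParams)
    smoothing_radii_um: list = field(default_factory=lambda: [25.0, 50.0])
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    cutpoint: CutpointConfig = field(default_factory=CutpointConfig)
    pixel_size_um: float | None = None  # override for images without calibration

    def validate(self) -> "PipelineConfig":
        # DetectionParams validates in __post_init__; re-run on merged values
        DetectionParams(**asdict(self.detection))
        if any(r <= 0 for r in self.smoothing_radii_um):
            raise ValueError("smoothing_radii_um must all be positive")
        self.classifier.validate()
        self.scoring.validate()
        self.cutpoint.validate()
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um override must be positive")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path | None, overrides: dict | None = None) -> "PipelineConfig":
        """Merge defaults, an optional YAML file, and flat CLI overrides."""
        data: dict = {}
        if path is not None:
            loaded = yaml.safe_load(Path(path).read_text()) or {}
            if not isinstance(loaded, dict):
                raise ValueError("config file must contain a mapping")
            data = loaded
        cfg = cls(
            detection=DetectionParams(**data.get("detection", {})),
            smoothing_radii_um=list(data.get("smoothing_radii_um", [25.0, 50.0])),
            classifier=ClassifierConfig(**data.get("classifier", {})),
            scoring=ScoringConfig(**data.get("scoring", {})),
            cutpoint=CutpointConfig(**data.get("cutpoint", {})),
            pixel_size_um=data.get("pixel_size_um"),
        )
        for key, value in (overrides or {}).items():
            if value is None:
                continue
            block, _, leaf = key.partition(".")
            if leaf:
                setattr(getattr(cfg, block), leaf, value)
            else:
                setattr(cfg, block, value)
        return cfg.validate()

    def to_dict(self) -> dict:
        return {
            "detection": asdict(self.detection),
            "smoothing_radii_um": list(self.smoothing_radii_um),
            "classifier": asdict(self.classifier),
            "scoring": asdict(self.scoring),
            "cutpoint": asdict(self.cutpoint),
            "pixel_size_um": self.pixel_size_um,
        }
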