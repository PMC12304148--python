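"""Single YAML config wiring all pipeline stages.

Layout::

    channels:                 # classification rules
      - {channel_index: 1, name: marker1, threshold: 60.0, enabled: true}
    intensity_method: ring    # or expanded_mean
    nuclear_channel: 0
    projection: max           # or mean, for z-stacks
    segmentation:
      backend: classical
      params: {smooth_sigma_um: 0.5, threshold_method: otsu, min_area_um2: 4.0}
    expansion:
      distance_um: 1.0
      mode: independent       # or exclusive
    roi:                      # optional polygon, (y, x) vertex pairs
      polygon: [[0, 0], [0, 100], [100, 100], [100, 0]]

The same file can be reused across runs to keep thresholds and settings
consistent between samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .classification import ClassificationConfig
from .errors import ConfigurationError
from .expansion import ExpansionSettings
from .image_io import RegionOfInterest

__all__ = ["PipelineConfig", "load_pipeline_config"]


@dataclass
class PipelineConfig:
    classification: ClassificationConfig
    expansion: ExpansionSettings = field(default_factory=ExpansionSettings)
    segmentation_backend: str = "classical"
    segmentation_params: dict = field(default_factory=dict)
    nuclear_channel: int = 0
    projection: str = "max"
    roi: RegionOfInterest = field(default_factory=RegionOfInterest.full_frame)

    def to_dict(self) -> dict:
        d = self.classification.to_dict()
        d["nuclear_channel"] = self.nuclear_channel
        d["projection"] = self.projection
        d["segmentation"] = {
            "backend": self.segmentation_backend,
            "params": dict(self.segmentation_params),
        }
        d["expansion"] = {
            "distance_um": self.expansion.distance_um,
            "mode": self.expansion.mode,
        }
        if not self.roi.is_full_frame:
            d["roi"] = {"polygon": np.asarray(self.roi.vertices).tolist()}
        return d

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        classification = ClassificationConfig.from_dict(d)
        exp = d.get("expansion", {}) or {}
        seg = d.get("segmentation", {}) or {}
        roi_block = d.get("roi")
        if roi_block and roi_block.get("polygon"):
            roi = RegionOfInterest(vertices=np.asarray(roi_block["polygon"], dtype=float))
        else:
            roi = RegionOfInterest.full_frame()
        return cls(
            classification=classification,
            expansion=ExpansionSettings(
                distance_um=float(exp.get("distance_um", 1.0)),
                mode=str(exp.get("mode", "independent")),
            ),
            segmentation_backend=str(seg.get("backend", "classical")),
            segmentation_params=dict(seg.get("params", {}) or {}),
            nuclear_channel=int(d.get("nuclear_channel", 0)),
            projection=str(d.get("projection", "max")),
            roi=roi,
        )


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    try:
        d = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse YAML config {path}: {exc}") from exc
    if not isinstance(d, dict):
        raise ConfigurationError(f"{path} does not contain a mapping")
    return PipelineConfig.from_dict(d)
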