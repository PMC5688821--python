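"""Pipeline configuration: serialisable bundle of all tunables."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .segmentation import HueRange, SegmentationConfig
from .traits import CalibrationStandard, MeasurementOptions


@dataclass
class PipelineConfig:
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    calibration: CalibrationStandard = field(default_factory=CalibrationStandard)
    measurement: MeasurementOptions = field(default_factory=MeasurementOptions)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def dump(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        seg = d.get("segmentation", {})
        hue_keys = {"holder_hue", "calyx_hue", "body_hue", "achene_hue"}
        seg = {
            k: (HueRange(**v) if k in hue_keys and isinstance(v, dict) else v)
            for k, v in seg.items()
        }
        return cls(
            segmentation=SegmentationConfig(**seg),
            calibration=CalibrationStandard(**d.get("calibration", {})),
            measurement=MeasurementOptions(**d.get("measurement", {})),
        )

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = (
            json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        )
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)
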