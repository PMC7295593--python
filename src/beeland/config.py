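"""Pipeline configuration: the study's fixed constants in one place.

Every run echoes its resolved configuration (all defaults filled in, plus a
content hash and the package version) next to its outputs, so a run is
reproducible from its outputs alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .segmentation import (
    DEFAULT_DISTANCE_CAP,
    DEFAULT_SPEED_CAP,
    DEFAULT_SPEED_THRESHOLD,
)
from .smoothing import SmootherSpec


@dataclass
class PipelineConfig:
    frame_rate: float = 100.0
    smoother_process_noise: tuple[float, float, float] = (1.0, 0.1, 0.01)
    smoother_measurement_noise: float = 1.0
    threshold: str | float = "auto"  # "auto" or a fixed value in m/s
    tl_speed_cap: float = DEFAULT_SPEED_CAP
    tl_distance_cap: float = DEFAULT_DISTANCE_CAP
    stats_transform: str = "auto"
    stats_reml: bool = True
    alpha: float = 0.05
    seed: int = 0
    pixel_noise_sd: float = 0.5

    def smoother_spec(self) -> SmootherSpec:
        return SmootherSpec(
            dt=1.0 / self.frame_rate,
            process_noise_diag=tuple(self.smoother_process_noise),
            measurement_noise=self.smoother_measurement_noise,
        )

    def resolved(self) -> dict:
        d = asdict(self)
        d["smoother_process_noise"] = list(d["smoother_process_noise"])
        blob = json.dumps(d, sort_keys=True)
        return {
            **d,
            "package_version": __version__,
            "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
        }

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.resolved(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.pop("package_version", None)
        data.pop("config_hash", None)
        if "smoother_process_noise" in data:
            data["smoother_process_noise"] = tuple(data["smoother_process_noise"])
        return cls(**data)

    @property
    def fixed_threshold(self) -> float | None:
        return None if self.threshold == "auto" else float(self.threshold)

    def threshold_or_default(self) -> float:
        return DEFAULT_SPEED_THRESHOLD if self.threshold == "auto" else float(self.threshold)
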