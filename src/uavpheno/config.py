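"""Pipeline configuration with paper-matching defaults."""
from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class PipelineConfig:
    # input paths
    captures_dir: str = "captures"
    panel_dir: str = "panel"
    cameras_csv: str = "cameras.csv"
    dsm_path: str = "dsm.tif"
    layout_path: str = "layout.geojson"
    output_dir: str = "out"

    # stages to run: subset of {"plants", "heads"}
    stages: tuple[str, ...] = ("plants", "heads")

    # detector parameters (defaults follow the published method where stated)
    ndvi_re_threshold: float = 0.3
    row_buffer_m: float = 0.10
    min_area_plants_px: int = 4
    min_area_heads_px: int = 10
    element_size: int = 3
    otsu_bins: int = 256
    kde_bandwidth_floor: float = 0.015

    # alignment
    alignment_mode: str = "per_flight"  # or "per_capture"
    alignment_samples: int = 5

    # nadir selection reference point: "centroid" or "midpoint"
    center_reference: str = "centroid"

    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - {"plants", "heads"}
        if unknown:
            raise ConfigurationError(f"unknown stages {unknown}")
        if self.alignment_mode not in ("per_flight", "per_capture"):
            raise ConfigurationError(f"unknown alignment mode {self.alignment_mode!r}")
        self.stages = tuple(self.stages)

    def resolve(self, root: str | Path) -> "PipelineConfig":
        """Return a copy with all paths made absolute against ``root``."""
        root = Path(root)
        d = asdict(self)
        for key in ("captures_dir", "panel_dir", "cameras_csv", "dsm_path",
                    "layout_path", "output_dir"):
            d[key] = str(root / d[key])
        return PipelineConfig(**d)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["stages"] = list(d["stages"])
        Path(path).write_text(yaml.safe_dump(d))
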