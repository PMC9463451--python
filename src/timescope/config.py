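"""Pipeline configuration with the published processing parameters as defaults.

Every stage parameter lives here with its canonical default: Gaussian
smoothing sigma 1 px, temporal FIR kernel (0.5, -1, 0.5), 7x7 median
window, 6-s background window, 7.5-px spot radius, quality threshold 1.6,
20-px max link distance, the per-window tracklet threshold arrays,
0.1%/10% vessel size gates, demons iterations [100, 50, 10, 1], 95%
retained PCA variance, and the 1.33 px/um pixel scale. Configurations
round-trip through JSON; unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

from .video import DEFAULT_PIXEL_PER_UM


@dataclasses.dataclass
class StabilizationConfig:
    enabled: bool = True
    transform_type: str = "rigid"
    blank_fraction: float = 0.75
    pyramid_levels: int = 4
    iterations_per_level: list[int] = dataclasses.field(
        default_factory=lambda: [100, 50, 10, 1])
    smoothing_sigma: float = 1.0


@dataclasses.dataclass
class VesselConfig:
    enabled: bool = True
    gaussian_sigma_px: float = 1.0
    fir_kernel: list[float] = dataclasses.field(
        default_factory=lambda: [0.5, -1.0, 0.5])
    median_window_px: int = 7
    min_area_frac: float = 0.001
    max_area_frac: float = 0.10
    closing_radius_px: int = 3


@dataclasses.dataclass
class TraffickingConfig:
    enabled: bool = True
    background_window_s: float = 6.0
    radius_px: float = 7.5
    quality_threshold: float = 1.6
    max_link_px: float = 20.0
    windows_s: list[float] = dataclasses.field(
        default_factory=lambda: [0.6, 0.8, 1.0])
    displacement_px: list[float] = dataclasses.field(
        default_factory=lambda: [20.5, 22.5, 22.5])
    consistency_deg: list[float] = dataclasses.field(
        default_factory=lambda: [58.0, 58.0, 58.0])
    quality: list[float] = dataclasses.field(
        default_factory=lambda: [1.6, 1.65, 1.75])


@dataclasses.dataclass
class SegmentationConfig:
    enabled: bool = False  # needs a trained segmenter
    input_size_px: int = 256
    learning_rate: float = 5e-2
    batch_size: int = 64
    epochs: int = 90


@dataclasses.dataclass
class PhenotypingConfig:
    enabled: bool = True
    n_clusters: str | int = "auto"
    variance_retained: float = 0.95


@dataclasses.dataclass
class ResponseConfig:
    enabled: bool = True
    mode: str = "specificity_first"
    max_features: int = 2
    cutoff: float = 0.5


@dataclasses.dataclass
class PipelineConfig:
    """Top-level configuration for :func:`timescope.pipeline.run_pipeline`."""

    seed: int = 0
    log_level: str = "INFO"
    frame_interval_s: float = 0.2
    pixel_per_um: float = DEFAULT_PIXEL_PER_UM
    stabilization: StabilizationConfig = dataclasses.field(
        default_factory=StabilizationConfig)
    vessels: VesselConfig = dataclasses.field(default_factory=VesselConfig)
    trafficking: TraffickingConfig = dataclasses.field(
        default_factory=TraffickingConfig)
    segmentation: SegmentationConfig = dataclasses.field(
        default_factory=SegmentationConfig)
    phenotyping: PhenotypingConfig = dataclasses.field(
        default_factory=PhenotypingConfig)
    response: ResponseConfig = dataclasses.field(default_factory=ResponseConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _build(cls, data, context="config")

    @classmethod
    def from_json(cls, source: str | Path) -> "PipelineConfig":
        path = Path(source)
        text = path.read_text() if path.exists() else str(source)
        # tolerate // comment lines for hand-edited configs
        lines = [ln for ln in text.splitlines()
                 if not ln.lstrip().startswith("//")]
        return cls.from_dict(json.loads("\n".join(lines)))


def _build(cls: type, data: dict, context: str) -> Any:
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown keys in {context}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        if isinstance(value, dict) and name in (
                "stabilization", "vessels", "trafficking", "segmentation",
                "phenotyping", "response"):
            sub_cls = fields[name].default_factory  # type: ignore[union-attr]
            kwargs[name] = _build(sub_cls, value, context=name)
        else:
            kwargs[name] = value
    return cls(**kwargs)
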