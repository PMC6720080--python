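"""Pipeline configuration: YAML in, validated blocks out.

Every block validates against its module's constraints at load time so
a malformed configuration fails before any stage runs.  The canonical
JSON serialization is hashed into a provenance id that is attached to
every numeric output row.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from conequant.cone_typing import HueWindows
from conequant.microglia import MicrogliaConfig
from conequant.preprocess import PreprocessConfig


@dataclass(frozen=True)
class ParticleFilterConfig:
    """Size window for particle analysis, px^2 at the working scale."""

    min_area_px2: float = 10.0
    max_area_px2: float = 2000.0

    def __post_init__(self) -> None:
        if not 0 <= self.min_area_px2 <= self.max_area_px2:
            raise ValueError("particle filter requires 0 <= min <= max")


@dataclass(frozen=True)
class ThresholdConfig:
    method: str = "otsu"
    fixed_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("otsu", "fixed"):
            raise ValueError("threshold method must be otsu or fixed")
        if self.method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed threshold method needs fixed_threshold")


@dataclass(frozen=True)
class QpcrConfig:
    calibrator: str = "WT"
    reference_genes: tuple[str, str] = ("GAPDH", "cyclophilin")
    default_efficiency: float = 2.0

    def __post_init__(self) -> None:
        if not 1.0 < self.default_efficiency <= 2.0:
            raise ValueError("default efficiency must be in (1, 2]")


def _hue_windows_from_dict(d: dict) -> HueWindows:
    def tup(intervals):
        return tuple(tuple(int(v) for v in iv) for iv in intervals)

    kwargs = {k: tup(v) for k, v in d.items() if k in ("red", "yellow", "green")}
    return HueWindows(**kwargs)


@dataclass
class PipelineConfig:
    """All stage parameters plus run-level seed and output directory."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    hue_windows: HueWindows = field(default_factory=HueWindows)
    particle_filter: ParticleFilterConfig = field(default_factory=ParticleFilterConfig)
    microglia: MicrogliaConfig = field(default_factory=MicrogliaConfig)
    qpcr: QpcrConfig = field(default_factory=QpcrConfig)
    seed: int = 0
    output_dir: str = "results"

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def block(key, factory, transform=None):
            sub = raw.get(key, {})
            if transform:
                return transform(sub)
            if isinstance(sub, dict):
                if "level_percentiles" in sub:
                    sub = dict(sub)
                    sub["level_percentiles"] = tuple(sub["level_percentiles"])
                if "reference_genes" in sub:
                    sub = dict(sub)
                    sub["reference_genes"] = tuple(sub["reference_genes"])
                return factory(**sub)
            raise ValueError(f"config block {key!r} must be a mapping")

        return cls(
            preprocess=block("preprocess", PreprocessConfig),
            threshold=block("threshold", ThresholdConfig),
            hue_windows=block("hue_windows", None, _hue_windows_from_dict),
            particle_filter=block("particle_filter", ParticleFilterConfig),
            microglia=block("microglia", MicrogliaConfig),
            qpcr=block("qpcr", QpcrConfig),
            seed=int(raw.get("seed", 0)),
            output_dir=str(raw.get("output_dir", "results")),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Short stable hash of the analysis parameters.

        The output directory is excluded: it does not affect any
        computed number.
        """
        payload = self.to_dict()
        payload.pop("output_dir", None)
        canon = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
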