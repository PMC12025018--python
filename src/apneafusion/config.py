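"""Single-file run configuration with lossless YAML round-trip and hashing."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .gradcam import BandConfig
from .ingest import LabelRule, SegmentationConfig
from .models import DropoutMode
from .quality import FilterConfig
from .synthetic import SimConfig
from .training import NoiseProtocol, NoiseScenario, SplitLevel, SplitPlan, TrainConfig

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs; every field mirrors a stage config."""

    sim: SimConfig = field(default_factory=SimConfig)
    n_records: int = 6
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    bandpass: FilterConfig = field(default_factory=FilterConfig)
    quality_percentile: float = 0.95
    split: SplitPlan = field(default_factory=SplitPlan)
    train: TrainConfig = field(default_factory=TrainConfig)
    head_hidden: tuple[int, ...] = (64,)
    dropout_mode: DropoutMode = DropoutMode.MATCHED_FS
    noise: NoiseProtocol = field(default_factory=NoiseProtocol)
    bands: BandConfig = field(default_factory=BandConfig)
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if hasattr(obj, "value") and not isinstance(obj, (int, float, str)):
                return obj.value
            if isinstance(obj, str) and hasattr(obj, "value"):  # str-mixin enums
                return str(obj.value)
            return obj

        d = asdict(self)
        d["segmentation"]["label_rule"] = self.segmentation.label_rule.value
        d["split"]["level"] = self.split.level.value
        d["dropout_mode"] = self.dropout_mode.value
        d["noise"]["scenarios"] = [s.value for s in self.noise.scenarios]
        return plain(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = dict(d.get("sim", {}))
        if "event_duration_s" in sim:
            sim["event_duration_s"] = tuple(sim["event_duration_s"])
        seg = dict(d.get("segmentation", {}))
        if "label_rule" in seg:
            seg["label_rule"] = LabelRule(seg["label_rule"])
        split = dict(d.get("split", {}))
        if "level" in split:
            split["level"] = SplitLevel(split["level"])
        if "ratios" in split:
            split["ratios"] = tuple(split["ratios"])
        noise = dict(d.get("noise", {}))
        if "scenarios" in noise:
            noise["scenarios"] = tuple(NoiseScenario(s) for s in noise["scenarios"])
        bands = dict(d.get("bands", {}))
        if "thresholds" in bands:
            bands["thresholds"] = tuple(bands["thresholds"])
        return cls(
            sim=SimConfig(**sim),
            n_records=d.get("n_records", 6),
            segmentation=SegmentationConfig(**seg),
            bandpass=FilterConfig(**d.get("bandpass", {})),
            quality_percentile=d.get("quality_percentile", 0.95),
            split=SplitPlan(**split),
            train=TrainConfig(**d.get("train", {})),
            head_hidden=tuple(d.get("head_hidden", (64,))),
            dropout_mode=DropoutMode(d.get("dropout_mode", "MATCHED_FS")),
            noise=NoiseProtocol(**noise),
            bands=BandConfig(**bands),
            seed=d.get("seed", 0),
            log_level=d.get("log_level", "INFO"),
        )


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def load_config(path: str | Path) -> RunConfig:
    return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()))


def config_hash(cfg: RunConfig) -> str:
    canonical = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
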