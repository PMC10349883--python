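"""Pipeline configuration.

Every tunable named in the module design decisions lives here so a single
YAML file can drive the whole pipeline.  Defaults reproduce the standard
analysis: 200-Hz analysis rate, 0.1–20 Hz band, amplitude/flat-line artifact
masking, envelope-threshold spindle detection, median-threshold slow-
oscillation detection, and a glmnet-style Elastic-Net grid.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Sequence

import yaml

logger = logging.getLogger("sleepsci")


def log_stage(stage: str, **params) -> None:
    """One structured log line per pipeline stage."""
    kv = " ".join(f"{k}={v}" for k, v in params.items())
    logger.info("stage=%s %s", stage, kv)


@dataclass
class PreprocessConfig:
    analysis_fs: float = 200.0          # Hz, analysis sampling rate
    bandpass_low: float = 0.1           # Hz
    bandpass_high: float = 20.0         # Hz
    filter_order: int = 4               # Butterworth, applied forward-backward
    amp_thresh_uv: float = 500.0        # artifact: absolute amplitude bound
    flat_sec: float = 5.0               # artifact: flat-line duration bound
    apply_ecg_correction: bool = False


@dataclass
class SpindleConfig:
    band: tuple[float, float] = (11.0, 15.0)    # Hz
    envelope_smooth_sec: float = 0.1
    threshold_sd: float = 1.5           # envelope > mean + k*sd over N2/N3
    merge_gap_sec: float = 0.25
    min_duration_sec: float = 0.5
    max_duration_sec: float = 3.0


@dataclass
class SlowOscConfig:
    band: tuple[float, float] = (0.2, 4.5)      # Hz
    min_duration_sec: float = 0.8
    max_duration_sec: float = 2.0


@dataclass
class SpectralConfig:
    subepoch_sec: float = 2.0
    total_band: tuple[float, float] = (0.5, 20.0)   # relative-power denominator
    bands: dict = field(default_factory=lambda: {
        "delta": (0.5, 4.0),
        "theta": (4.0, 8.0),
        "alpha": (8.0, 12.0),
        "sigma": (11.0, 15.0),
    })


@dataclass
class ModelConfig:
    n_outer_folds: int = 10
    n_inner_folds: int = 10
    l1_ratios: Sequence[float] = (0.1, 0.5, 0.7, 0.9, 0.95, 1.0)
    n_alphas: int = 50
    alpha_eps: float = 1e-4             # lambda path spans 4 decades below lambda_max
    knn_k: int = 10
    max_iter: int = 2000


@dataclass
class MacroConfig:
    rem_latency_from_onset: bool = False  # default: from lights off


@dataclass
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    spindle: SpindleConfig = field(default_factory=SpindleConfig)
    slow_osc: SlowOscConfig = field(default_factory=SlowOscConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    macro: MacroConfig = field(default_factory=MacroConfig)
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cfg = cls()
        for section_name, section in raw.items():
            if not hasattr(cfg, section_name):
                raise KeyError(f"unknown config section {section_name!r}")
            target = getattr(cfg, section_name)
            if dataclasses.is_dataclass(target):
                names = {f.name for f in dataclasses.fields(target)}
                for k, v in section.items():
                    if k not in names:
                        raise KeyError(f"unknown config key {section_name}.{k}")
                    current = getattr(target, k)
                    if isinstance(current, tuple) and isinstance(v, list):
                        v = tuple(v)
                    setattr(target, k, v)
            else:
                setattr(cfg, section_name, section)
        return cfg
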