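"""Pipeline configuration.

All tunable parameters of the preprocessing, network, training and detection
stages live here, grouped by stage, with the published defaults. Configs are
plain dataclasses and round-trip to YAML so a whole run is reproducible from
one file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Sequence

import yaml

EPOCH_LEN_S = 30.0
TARGET_FS = 4.0  # Hz of the per-epoch network input
EPOCH_SAMPLES = int(EPOCH_LEN_S * TARGET_FS)  # 120


@dataclass
class EcgConfig:
    """Tachogram preprocessing parameters."""

    min_beats: int = 15            # epochs with fewer detected R-peaks are discarded
    ihr_low_bpm: float = 40.0      # physiological lower bound
    ihr_high_bpm: float = 180.0    # physiological upper bound
    median_band_bpm: float = 20.0  # allowed deviation from the epoch median
    sd_multiplier: float = 3.0     # allowed deviation in units of the epoch SD
    max_gap_samples: int = 10      # longest NaN run repairable by mirroring (2.5 s at 4 Hz)
    refractory_s: float = 0.25     # R-peak detector refractory period


@dataclass
class RipConfig:
    """Respiratory-effort preprocessing parameters."""

    band_hz: tuple = (0.04, 2.0)   # passband of the zero-phase Butterworth filter
    filter_order: int = 4
    # autoregressive edge extension per border before filtering; the 0.04 Hz
    # edge settles with a ~10 s time constant, so the pad must dwarf it
    edge_pad_s: float = 60.0
    ar_order: int = 24             # AR model order of the edge extension (1 s at 4 Hz x fs/4)


@dataclass
class ArchConfig:
    """Network architecture: per-branch conv stack and dense head."""

    conv: Sequence[tuple] = ((8, 7, 2), (16, 5, 2), (32, 3, 2))  # (filters, kernel, stride)
    dense: int = 64
    dropout: float = 0.5
    n_classes: int = 2


@dataclass
class TrainConfig:
    """Optimization settings (Adam, balanced batches of 16)."""

    batch_size: int = 16
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    max_epochs: int = 100
    patience: int = 10
    val_fraction: float = 0.3
    seed: int = 0


@dataclass
class DetectConfig:
    """OSA screening thresholds on the uncertainty metrics (percent)."""

    threshold_pct_use: float = 64.0
    threshold_pct_swt: float = 24.0
    min_specificity: float = 0.95
    osa_ahi_cutoff: float = 15.0
    train_ahi_cutoff: float = 10.0


@dataclass
class PipelineConfig:
    ecg: EcgConfig = field(default_factory=EcgConfig)
    rip: RipConfig = field(default_factory=RipConfig)
    arch: ArchConfig = field(default_factory=ArchConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rip"]["band_hz"] = list(self.rip.band_hz)
        d["arch"]["conv"] = [list(c) for c in self.arch.conv]
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls()
        for section_name, section_cls in (
            ("ecg", EcgConfig), ("rip", RipConfig), ("arch", ArchConfig),
            ("train", TrainConfig), ("detect", DetectConfig),
        ):
            sub = d.get(section_name, {})
            known = {f.name for f in fields(section_cls)}
            unknown = set(sub) - known
            if unknown:
                raise ValueError(f"unknown {section_name} config keys: {sorted(unknown)}")
            kwargs = dict(sub)
            if section_name == "rip" and "band_hz" in kwargs:
                kwargs["band_hz"] = tuple(kwargs["band_hz"])
            if section_name == "arch" and "conv" in kwargs:
                kwargs["conv"] = tuple(tuple(c) for c in kwargs["conv"])
            setattr(cfg, section_name, section_cls(**kwargs))
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
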