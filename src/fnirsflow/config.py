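"""Declarative pipeline configuration.

One YAML file describes an end-to-end run; the schema is strict (unknown keys
rejected) and every stochastic stage derives its seed from the single
top-level ``seed``.  ``config_hash`` stamps artifacts so a report can always
be traced to the exact settings that produced it.
"""

from __future__ import annotations

import hashlib
import json
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "PipelineConfig", "load_config", "config_hash",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ParadigmBlock(_Strict):
    brands: list[str] = ["coca", "pepsi"]
    durations_s: list[float] = [15.0, 30.0, 60.0]
    initial_rest_s: float = 120.0
    repeats_per_section: int = 2
    notification_s: float = 2.0
    rating_s: float = 5.0
    rest_s: float = 30.0
    #: one preference label per trial; None -> balanced default cycle
    labels: Optional[list[str]] = None


class GeometryBlock(_Strict):
    source_detector_distance_cm: float = 2.828
    dpf_690: float = 6.0
    dpf_830: float = 6.0


class ExtinctionBlock(_Strict):
    eps_hbo_690: float = 0.95
    eps_hbr_690: float = 4.93
    eps_hbo_830: float = 2.135
    eps_hbr_830: float = 1.791


class FilterBlock(_Strict):
    order: int = 4
    fc_hz: float = 0.15
    detrend: Literal["linear", "dct"] = "linear"
    #: filter concentrations (default) or OD before conversion
    domain: Literal["concentration", "od"] = "concentration"


class EpochBlock(_Strict):
    #: "auto" = full video phase; "table3" = printed 208/416/832 preset;
    #: an integer fixes the length directly
    m_samples: int | Literal["auto", "table3"] = "auto"
    #: sliding-window augmentation (samples); None disables augmentation
    window_len: Optional[int] = None
    stride: int = 13
    #: cap on augmented windows per trial (balances classes across durations)
    max_windows_per_trial: Optional[int] = None


class NetworkBlock(_Strict):
    variant: str = "CNN3-a"
    compat_table3: bool = False
    dropout_rate: float = 0.5


class TrainBlock(_Strict):
    epochs: int = 100
    batch_size: int = 8
    learning_rate: float = 0.0005
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1.0e-8


class EvaluationBlock(_Strict):
    k: int = 8
    #: e.g. ["like", "dislike"]; None runs the 3-class problem
    pair: Optional[list[str]] = None
    normalize: bool = True


class SimulationBlock(_Strict):
    class_amplitudes: dict[str, float] = Field(
        default_factory=lambda: {"like": 1.0, "so-so": 0.5, "dislike": 0.1})
    active_channels: list[int] = Field(default_factory=lambda: list(range(1, 7)))
    vlf_amp: float = 0.05        # 0.03 Hz, uM
    respiration_amp: float = 0.05  # 0.2 Hz
    cardiac_amp: float = 0.05    # 0.8 Hz
    white_sd: float = 0.05
    drift_slope: float = 2.0e-4
    hbr_coupling: float = 1.0 / 3.0
    #: also synthesize raw optical intensities and convert them back
    roundtrip_optical: bool = False


class TMapBlock(_Strict):
    alpha: float = 0.05


class PipelineConfig(_Strict):
    seed: int = 0
    fs: float = 15.625
    log_level: str = "INFO"
    paradigm: ParadigmBlock = Field(default_factory=ParadigmBlock)
    geometry: GeometryBlock = Field(default_factory=GeometryBlock)
    extinction: ExtinctionBlock = Field(default_factory=ExtinctionBlock)
    filter: FilterBlock = Field(default_factory=FilterBlock)
    epochs: EpochBlock = Field(default_factory=EpochBlock)
    network: NetworkBlock = Field(default_factory=NetworkBlock)
    train: TrainBlock = Field(default_factory=TrainBlock)
    evaluation: EvaluationBlock = Field(default_factory=EvaluationBlock)
    simulation: SimulationBlock = Field(default_factory=SimulationBlock)
    tmap: TMapBlock = Field(default_factory=TMapBlock)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


def config_hash(config: PipelineConfig) -> str:
    """Short stable digest of the full configuration."""
    canon = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
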