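"""Run configuration: one validated document covering every pipeline stage.

Loaded from YAML or JSON; unknown keys are rejected so typos fail loudly.
``RunConfig.model_json_schema()`` publishes the schema.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .bp import TrainConfig
from .ica import IcaConfig
from .preprocessing import PreprocessConfig


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridSettings(_Strict):
    rows: int = 8
    cols: int = 8
    pitch_mm: float = Field(10.0, gt=0)


class SimulatorSettings(_Strict):
    n_sources: int = 5
    postures: list[str] = ["N", "S"]
    cycles: int = 5
    cycle_s: float = 3.0
    rest_s: float = 5.0
    snr_db: Optional[float] = 20.0
    powerline_hz: float = 50.0
    powerline_amplitude: float = 0.0
    source_spread_mm: Optional[float] = None   # default: one pitch
    force_gain_n: float = 40.0
    force_noise_sd_n: float = 0.0
    dominance_gain: float = 0.4


class PreprocessSettings(_Strict):
    band_low_hz: float = 20.0
    band_high_hz: float = 450.0
    filter_order: int = 4
    window_s: float = 0.5
    step_s: float = 0.2
    notch_hz: Optional[float] = None
    notch_halfwidth_hz: float = 2.0

    def to_dataclass(self) -> PreprocessConfig:
        return PreprocessConfig(**self.model_dump())


class IcaSettings(_Strict):
    n_components: int = 5
    max_iter: int = 1000
    tol: float = 1e-4
    learning_rate: float = 0.020

    def to_dataclass(self, seed: int = 0) -> IcaConfig:
        return IcaConfig(seed=seed, **self.model_dump())


class LocalizationSettings(_Strict):
    emg_band_low_hz: float = 20.0
    emg_band_high_hz: float = 450.0
    threshold: float = 0.7
    powerline_hz: float = 50.0
    notch_halfwidth_hz: float = 2.0


class TrainSettings(_Strict):
    learning_rate: float = 0.3
    momentum: float = 0.9
    target_error: float = 0.001
    max_epochs: int = 1000
    hidden_layers: list[int] = [5, 5]
    validation_fraction: float = 0.0

    def to_dataclass(self, seed: int = 0) -> TrainConfig:
        d = self.model_dump()
        d.pop("hidden_layers")
        return TrainConfig(seed=seed, **d)


class EvaluationSettings(_Strict):
    train_ratio: float = 0.8
    test_ratio: float = 0.2
    cv_folds: int = 5
    active_threshold_fraction: float = 0.05   # of peak actual force
    classification_threshold_pct_mvc: Optional[float] = None


class RunConfig(_Strict):
    """Top-level configuration for a full pipeline run."""

    seed: int = 0
    fs_hz: float = 1000.0
    grid: GridSettings = GridSettings()
    simulator: SimulatorSettings = SimulatorSettings()
    preprocess: PreprocessSettings = PreprocessSettings()
    ica: IcaSettings = IcaSettings()
    localization: LocalizationSettings = LocalizationSettings()
    train: TrainSettings = TrainSettings()
    evaluation: EvaluationSettings = EvaluationSettings()
    # paths to a recorded dataset; when absent the simulator supplies the data
    recording_csv: Optional[str] = None
    recording_sidecar: Optional[str] = None
    mvc_trial_csvs: list[str] = []


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return RunConfig.model_validate(data or {})
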