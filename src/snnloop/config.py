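"""Declarative experiment configuration.

An :class:`ExperimentConfig` fully describes a run: substrate, network,
task, loss, and training hyperparameters plus sweep grids.  Configs are
schema-validated (unknown keys are rejected) and every runner archives the
resolved configuration next to its outputs, so a run is reproducible from
``(config, seed)`` alone.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Optional

import yaml
from pydantic import BaseModel, ConfigDict, field_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SubstrateSection(_Strict):
    """Analog-substrate emulation. ``enabled=False`` trains purely in
    software (no quantization, no recordings)."""

    enabled: bool = True
    dt: float = 1.0
    substeps: int = 10
    integration: str = "exact"
    tau_mem: float = 20.0
    tau_syn: float = 10.0
    mismatch_sigma: float = 0.0
    mismatch_which: List[str] = ["tau_mem", "tau_syn", "threshold"]
    membrane_noise_sd: float = 0.01
    sample_jitter_sd: float = 0.01
    refractory_substeps: int = 0
    fan_in_limit: int = 256

    @field_validator("integration")
    @classmethod
    def _integration(cls, v):
        if v not in ("exact", "grid"):
            raise ValueError("integration must be 'exact' or 'grid'")
        return v


class NetworkSection(_Strict):
    n_hidden: int = 64
    recurrent: bool = False
    sigma_w: float = 1.0
    scale_hidden: float = 100.0
    quantize: bool = True


class TaskSection(_Strict):
    """Synthetic task description; ``dataset_path`` substitutes a real
    event dataset in the supported HDF5 layout for the generated one."""

    kind: str = "latency_images"
    n_classes: int = 10
    n_channels: int = 70
    samples_per_class: int = 100
    held_out_fraction: float = 0.2
    disjoint_split: bool = False
    duration: float = 100.0
    # latency-image task
    pixel_noise_sd: float = 0.12
    rotation_max_deg: float = 0.0
    tau_in: float = 20.0
    theta_in: float = 0.2
    t_max: float = 60.0
    # temporal-pattern task
    time_jitter_sd: float = 2.0
    channel_jitter_sd: float = 0.5
    deletion_p: float = 0.1
    background_events: float = 4.0
    anchors_per_class: int = 24
    dataset_path: Optional[str] = None

    @field_validator("kind")
    @classmethod
    def _kind(cls, v):
        if v not in ("latency_images", "temporal_patterns"):
            raise ValueError("task kind must be 'latency_images' or 'temporal_patterns'")
        return v


class LossSection(_Strict):
    mode: str = "max_over_time"
    rho_a: float = 0.0
    rho_b: float = 0.0
    rho_r: float = 0.0
    theta_r: float = 0.0
    beta: float = 10.0
    surrogate_form: str = "superspike"


class TrainingSection(_Strict):
    lr: float = 2e-3
    lr_decay: float = 1.0
    n_epochs: int = 30
    batch_size: int = 50
    shuffle: bool = True
    dropout_rate: float = 0.0
    grad_clip: Optional[float] = None


class ExperimentSection(_Strict):
    """Sweep grids and replicate seeds for the experiment runners."""

    seeds: List[int] = [0, 1, 2]
    sigma_grid: List[float] = [0.0, 0.1, 0.2, 0.3, 0.4, 0.5]
    rho_b_grid: List[float] = [0.0, 1e-4, 1e-3, 1e-2, 1e-1]
    dropout_rates: List[float] = [0.0, 0.4]
    ablation_fractions: List[float] = [0.0, 0.05, 0.15, 0.3]


class ExperimentConfig(_Strict):
    seed: int = 0
    substrate: SubstrateSection = SubstrateSection()
    network: NetworkSection = NetworkSection()
    task: TaskSection = TaskSection()
    loss: LossSection = LossSection()
    training: TrainingSection = TrainingSection()
    experiment: ExperimentSection = ExperimentSection()

    def resolved_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=True)


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML config file; unknown keys raise."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    return ExperimentConfig.model_validate(raw)


def apply_overrides(cfg: ExperimentConfig, overrides) -> ExperimentConfig:
    """Apply ``section.key=value`` overrides (values parsed as YAML)."""
    data = cfg.model_dump()
    for item in overrides:
        key, _, value = item.partition("=")
        if not _:
            raise ValueError(f"override {item!r} is not of the form key=value")
        node = data
        parts = key.strip().split(".")
        for p in parts[:-1]:
            if p not in node:
                raise KeyError(f"unknown config section {p!r}")
            node = node[p]
        if parts[-1] not in node:
            raise KeyError(f"unknown config key {key!r}")
        node[parts[-1]] = yaml.safe_load(value)
    return ExperimentConfig.model_validate(data)


def archive_config(cfg: ExperimentConfig, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "resolved_config.yaml").write_text(cfg.resolved_yaml())
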