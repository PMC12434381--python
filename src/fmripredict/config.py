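"""Run configuration: YAML schema with strict validation.

Unknown keys are rejected (with the offending field path in the message),
defaults are filled, and a loaded config round-trips through save/load.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .features import FEATURE_NAMES
from .prediction import MODEL_NAMES
from .synthetic import BINARY_TARGET, CONTINUOUS_TARGETS, CohortConfig
from .preprocess import PreprocessConfig

TARGET_NAMES = CONTINUOUS_TARGETS + (BINARY_TARGET,)


class ConfigError(ValueError):
    """Invalid or unreadable run configuration."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CohortSection(_Strict):
    n_subjects: int = 40
    n_regions: int = 274
    n_sessions: int = 4
    frames_per_session: int = 1200
    tr_seconds: float = 0.72
    n_communities: int = 5
    family_size_probs: list[float] = [0.40, 0.35, 0.15, 0.07, 0.03]
    effect_size_per_target: dict[str, float] = Field(default_factory=dict)
    informative_feature: dict[str, str] = Field(default_factory=dict)
    spectral_decay: float = 2.0
    noise_sd: float = 0.5
    seed: int = 0


class PreprocessSection(_Strict):
    n_discard: int = 6
    highpass_hz: float = 0.01
    motion: bool = True
    motion_derivatives: bool = True
    linear_trend: bool = True


class SchemeSection(_Strict):
    n_outer_splits: int = 10
    test_fraction: float = 0.15
    n_inner_folds: int = 3


class ScalingSection(_Strict):
    enabled: bool = False
    feature: str = "fc"
    target: str = "cognition"
    model: str = "krr"
    train_fractions: list[float] = [0.2, 0.4, 0.6, 0.8, 1.0]
    session_amounts: list[float] = [0.25, 0.5, 1.0, 2.0, 4.0]


class RunConfig(_Strict):
    """Top-level run configuration (see the README for a worked example)."""

    cohort_dir: str
    output_dir: str
    cohort: Optional[CohortSection] = None
    preprocess: PreprocessSection = Field(default_factory=PreprocessSection)
    features: list[str] = list(FEATURE_NAMES)
    targets: list[str] = list(TARGET_NAMES)
    models: list[str] = list(MODEL_NAMES)
    scheme: SchemeSection = Field(default_factory=SchemeSection)
    permutations: int = 100
    scaling: Optional[ScalingSection] = None
    master_seed: int = 0

    @field_validator("features")
    @classmethod
    def _known_features(cls, v):
        for name in v:
            if name not in FEATURE_NAMES:
                raise ValueError(f"unknown feature {name!r}; expected one of {FEATURE_NAMES}")
        return v

    @field_validator("targets")
    @classmethod
    def _known_targets(cls, v):
        for name in v:
            if name not in TARGET_NAMES:
                raise ValueError(f"unknown target {name!r}; expected one of {TARGET_NAMES}")
        return v

    @field_validator("models")
    @classmethod
    def _known_models(cls, v):
        for name in v:
            if name not in MODEL_NAMES:
                raise ValueError(f"unknown model {name!r}; expected one of {MODEL_NAMES}")
        return v

    def cohort_config(self) -> CohortConfig:
        if self.cohort is None:
            raise ConfigError("config has no cohort section")
        kwargs = self.cohort.model_dump()
        kwargs["family_size_probs"] = tuple(kwargs["family_size_probs"])
        if not kwargs["effect_size_per_target"]:
            kwargs.pop("effect_size_per_target")
        if not kwargs["informative_feature"]:
            kwargs.pop("informative_feature")
        return CohortConfig(**kwargs)

    def preprocess_config(self) -> PreprocessConfig:
        return PreprocessConfig(**self.preprocess.model_dump())


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config; unknown keys are an error."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping")
    try:
        return RunConfig.model_validate(raw)
    except Exception as exc:  # pydantic.ValidationError carries field paths
        raise ConfigError(str(exc)) from exc


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))
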