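"""Pipeline configuration: schema, validation and loading.

Configs are YAML or JSON.  Validation is pydantic-based so that schema
violations are reported with full field paths.  All tabular output is
delimiter-explicit (TSV for genetic matrices, CSV for results), UTF-8,
no locale-dependent number formatting.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, ValidationError

__all__ = ["PipelineConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Configuration invalid; message lists offending field paths."""


class GeneratorConfig(BaseModel):
    n_individuals: int = 5_000
    n_variants: int = 20
    prevalence: float = 0.043
    beta_cost: float = 800.0
    beta_qaly: float = -0.05
    confounder_effects: tuple[float, float, float] = (0.5, 400.0, -0.04)
    cost_noise_sd: float = 1200.0
    qaly_noise_sd: float = 0.15
    sex_ratio: float = 0.463
    n_centres: int = 8
    n_pcs: int = 10
    missing_rate: float = 0.0
    sex_specific: str | None = None


class AnalysisConfig(BaseModel):
    scheme: str = "beta"  # PRS weighting: 'beta' or 'precision'
    robust: str = "HC1"
    n_pcs: int = 10
    m_imputations: int = 5
    strata: list[str] = Field(default_factory=list)  # 'sex', 'age_band', ...
    outcomes: list[str] = Field(
        default_factory=lambda: ["annual_cost", "annual_qaly"])


class CountsConfig(BaseModel):
    n_cases: int
    n_total: int
    label: str = "all"


class EffectsConfig(BaseModel):
    cost_effect: float
    cost_ci95: tuple[float, float]
    qaly_effect: float
    qaly_ci95: tuple[float, float]
    source: str = "mendelian_randomization"


class InterventionConfig(BaseModel):
    counts: CountsConfig
    or_point: float = 0.29
    or_ci95: tuple[float, float] = (0.13, 0.65)
    drug_cost_monthly: float = 39.20
    months_per_year: int = 12
    wtp_threshold: float = 20_000.0
    n_draws: int = 10_000
    or_scale: str = "log"
    # None: take effect estimates from the mr stage's results CSV
    effects: EffectsConfig | None = None


class PathsConfig(BaseModel):
    cohort: str | None = None
    dosages: str | None = None
    weights: str | None = None
    prs: str | None = None
    mr_results: str | None = None


class PipelineConfig(BaseModel):
    seed: int = 0
    generator: GeneratorConfig = Field(default_factory=GeneratorConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    intervention: InterventionConfig | None = None
    paths: PathsConfig = Field(default_factory=PathsConfig)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> PipelineConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text(encoding="utf-8")
    data = (json.loads(text) if path.suffix == ".json"
            else yaml.safe_load(text))
    try:
        return PipelineConfig.model_validate(data or {})
    except ValidationError as e:
        lines = [".".join(str(p) for p in err["loc"]) + ": " + err["msg"]
                 for err in e.errors()]
        raise ConfigError("invalid config:\n  " + "\n  ".join(lines)) from e
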