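"""Single-YAML run configuration.

One file (plus one seed) fully determines a pipeline run; all randomness is
routed through seeds derived from the top-level ``seed``.  Unknown keys are
rejected by name so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .features import FeatureConfig
from .imputation import ImputationConfig
from .models import DEFAULT_GRIDS, EvalConfig
from .synthetic_cohort import CohortConfig


class ConfigError(ValueError):
    pass


def _build(cls, data: dict, section: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {section!r}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class RunConfig:
    """Everything a run needs: stage configs, model choice, seed."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)
    model_family: str = "logreg_l1"
    model_grid: dict = field(default_factory=dict)
    explain_samples: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.model_grid:
            self.model_grid = {k: list(v)
                               for k, v in DEFAULT_GRIDS[self.model_family].items()}
        # route every stochastic stage through the single top-level seed
        self.cohort.seed = self.seed

    @classmethod
    def from_yaml(cls, path, seed: int | None = None) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sections = {"cohort": CohortConfig, "imputation": ImputationConfig,
                    "features": FeatureConfig, "evaluation": EvalConfig}
        allowed = set(sections) | {"model_family", "model_grid",
                                   "explain_samples", "seed"}
        unknown = set(raw) - allowed
        if unknown:
            raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
        kwargs = {}
        for name, sub_cls in sections.items():
            if name in raw:
                sub = raw[name]
                if name == "cohort" and "monitoring_days_range" in sub:
                    sub["monitoring_days_range"] = tuple(
                        sub["monitoring_days_range"])
                if name == "features" and "dfa_windows" in sub:
                    sub["dfa_windows"] = tuple(sub["dfa_windows"])
                kwargs[name] = _build(sub_cls, sub, name)
        for name in ("model_family", "model_grid", "explain_samples", "seed"):
            if name in raw:
                kwargs[name] = raw[name]
        if seed is not None:
            kwargs["seed"] = seed
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
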