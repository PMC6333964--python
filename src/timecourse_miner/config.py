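"""Application configuration with documented, file-loadable defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

from .timepoints import EngineConfig, UNIT_FACTORS

__all__ = ["AppConfig", "load_config", "default_config_path"]


@dataclass
class AppConfig:
    """Everything tunable about the pipeline, in one place.

    Loading the shipped ``default_config.yaml`` reproduces exactly these
    defaults; a user config may override any subset of keys.
    """

    unit_factors: dict[str, float] = field(default_factory=lambda: dict(UNIT_FACTORS))
    keyword_window: int = 2
    count_keywords: list[str] = field(default_factory=lambda: [
        "sample", "samples", "patient", "patients", "subject", "subjects",
    ])
    progression_rel_tol: float = 1e-6
    dedupe_rel_tol: float = 1e-9
    ontology_path: str = ""
    output_format: str = "jsonl"
    log_level: str = "INFO"
    seed: int = 42

    def engine_config(self) -> EngineConfig:
        return EngineConfig(
            keyword_window=self.keyword_window,
            count_keywords=tuple(self.count_keywords),
            progression_rel_tol=self.progression_rel_tol,
            dedupe_rel_tol=self.dedupe_rel_tol,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def default_config_path() -> Path:
    ref = resources.files("timecourse_miner.data").joinpath("default_config.yaml")
    with resources.as_file(ref) as path:
        return Path(path)


def load_config(path: Optional[str | Path] = None) -> AppConfig:
    """Load a YAML config; unknown keys are rejected, missing keys default."""
    if path is None:
        return AppConfig()
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    known = set(AppConfig.__dataclass_fields__)
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    return AppConfig(**data)
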