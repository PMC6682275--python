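"""Declarative pipeline configuration."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit code 1 at the CLI)."""


class DataError(ValueError):
    """Malformed or inconsistent input data (exit code 2 at the CLI)."""


@dataclass
class PipelineConfig:
    """Paths and tuning knobs for one end-to-end run.

    ``split_date`` (ISO date) is the first local date of the test period;
    earlier dates train the baseline models, later ones are scanned for
    deviations.
    """

    tweets_path: str
    gazetteer_path: str
    weather_path: str
    lexicon_path: str
    output_dir: str
    split_date: str
    lang: str = "en"
    celebrity_threshold: int = 300_000
    min_n: int = 1
    alpha: float = 0.05
    top_k: int = 50
    top_cities: int | None = None
    outcomes: tuple[str, ...] = ("p_neg", "p_pos")
    weight_by_n: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tweets_path", "gazetteer_path", "weather_path", "lexicon_path",
                     "output_dir", "split_date"):
            if not getattr(self, name):
                raise ConfigError(f"missing required config field: {name}")
        paths = [self.tweets_path, self.gazetteer_path, self.weather_path, self.lexicon_path]
        if len(set(paths)) != len(paths):
            raise ConfigError("input paths must be distinct")
        if self.min_n < 1:
            raise ConfigError("min_n must be >= 1")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must be in (0, 1)")
        for oc in self.outcomes:
            if oc not in ("p_pos", "p_neg"):
                raise ConfigError(f"unknown outcome {oc!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        try:
            cfg = cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        if isinstance(cfg.outcomes, list):
            cfg.outcomes = tuple(cfg.outcomes)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["outcomes"] = list(self.outcomes)
        return d
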