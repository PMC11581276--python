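"""Run configuration: schema validation, loading, and event serialization."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constant import TruncationSpec
from .errors import ConfigError, DomainError, SpecError
from .intensity import Interval, intensity_from_config

__all__ = ["RunConfig", "load_config", "write_events_csv",
           "write_events_ndjson", "config_hash"]

_SAMPLERS = {"auto", "thinning", "inversion", "orderstats", "step", "linear",
             "loglinear", "constant"}
_FORMATS = {"csv", "csv-wide", "ndjson"}


@dataclass
class RunConfig:
    """Validated drawing-run configuration."""

    intensity: dict
    n_draws: int = 1
    seed: int = 0
    stream_id: str | None = None
    sampler: str = "auto"
    interval: list | None = None
    truncation: dict = field(default_factory=dict)
    majorizer: dict | None = None
    output_format: str = "csv"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "intensity" not in raw:
            raise ConfigError("config requires an 'intensity' section")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        try:
            self.build_model()
        except SpecError as exc:
            raise ConfigError(f"bad intensity spec: {exc}") from exc
        if self.sampler not in _SAMPLERS:
            raise ConfigError(f"sampler must be one of {sorted(_SAMPLERS)}")
        if not (isinstance(self.n_draws, int) and self.n_draws >= 1):
            raise ConfigError("n_draws must be a positive integer")
        if not (isinstance(self.seed, int) and self.seed >= 0):
            raise ConfigError("seed must be a non-negative integer")
        if self.output_format not in _FORMATS:
            raise ConfigError(f"output_format must be one of {sorted(_FORMATS)}")
        if self.interval is not None:
            if len(self.interval) != 2:
                raise ConfigError("interval must be [a, b]")
            try:
                Interval(*self.interval)
            except (DomainError, TypeError) as exc:
                raise ConfigError(f"bad interval: {exc}") from exc
        try:
            self.build_truncation()
        except SpecError as exc:
            raise ConfigError(f"bad truncation: {exc}") from exc

    def build_model(self):
        return intensity_from_config(self.intensity)

    def build_truncation(self) -> TruncationSpec:
        t = self.truncation or {}
        return TruncationSpec(at_least_m=t.get("at_least_m", 0),
                              at_most_k=t.get("at_most_k"),
                              exactly_n=t.get("exactly_n"))

    def build_interval(self):
        if self.interval is not None:
            return Interval(*self.interval)
        return self.build_model().domain

    def to_dict(self) -> dict:
        return {"intensity": self.intensity, "n_draws": self.n_draws,
                "seed": self.seed, "stream_id": self.stream_id,
                "sampler": self.sampler, "interval": self.interval,
                "truncation": self.truncation, "majorizer": self.majorizer,
                "output_format": self.output_format}


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load a JSON or YAML run configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml
        raw = yaml.safe_load(text)
    else:
        try:
            raw = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return RunConfig.from_dict(raw)


def write_events_csv(series_list, path, *, wide: bool = False) -> None:
    """Long format: header ``draw_id,event_index,time``; wide format: one
    ragged comma-padded row per draw."""
    if wide:
        from .special import event_matrix_to_csv
        ncol = max((len(s) for s in series_list), default=0)
        mat = np.full((len(series_list), ncol), np.nan)
        for i, s in enumerate(series_list):
            mat[i, :len(s)] = s
        event_matrix_to_csv(mat, path)
        return
    with open(path, "w") as fh:
        fh.write("draw_id,event_index,time\n")
        for i, series in enumerate(series_list):
            for k, t in enumerate(series):
                fh.write(f"{i},{k},{float(t)!r}\n")


def write_events_ndjson(series_list, path) -> None:
    with open(path, "w") as fh:
        for series in series_list:
            fh.write(json.dumps([float(t) for t in series]) + "\n")
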