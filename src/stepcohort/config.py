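"""Analysis configuration: every numeric constant of the step-counter analysis.

The defaults encode the study protocol this package implements: a day counts
as *active* (device worn) when it records at least 100 steps; step-counter use
is considered terminated after the last run of at least 4 consecutive active
days; walking activity is classified on the graduated step index
(low < 3000, medium 3000-9999, high >= 10,000 steps/day); and weekly means
are evaluated at fixed checkpoints (day 7 and months 1, 3, 6, 9, 12) over a
365-day monitoring horizon.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["AnalysisConfig", "load_config", "save_config"]

DEFAULT_CHECKPOINTS = (7, 30, 90, 180, 270, 365)


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and checkpoints governing the whole pipeline.

    Parameters
    ----------
    active_day_cutoff : int
        Minimum steps/day for a day to count as active (device worn).
        Inclusive: a day with exactly ``active_day_cutoff`` steps is active.
    min_consecutive_active : int
        Run length (in days) that defines a qualifying run; the final day of
        use is the last day of the last such run.
    low_threshold, high_threshold : float
        Graduated step index boundaries: grand mean < ``low_threshold`` is
        low activity, >= ``high_threshold`` is high activity, else medium.
    checkpoints : tuple of int
        Study days at which weekly means are evaluated.
    window_days : int
        Length of the checkpoint window; the window is the ``window_days``
        days ending at (and including) the checkpoint day.
    horizon : int
        Length of the monitoring period in study days (day 1 = inclusion).
    """

    active_day_cutoff: int = 100
    min_consecutive_active: int = 4
    low_threshold: float = 3000.0
    high_threshold: float = 10000.0
    checkpoints: tuple[int, ...] = DEFAULT_CHECKPOINTS
    window_days: int = 7
    horizon: int = 365

    def __post_init__(self) -> None:
        object.__setattr__(self, "checkpoints", tuple(int(c) for c in self.checkpoints))
        if not 0 < self.low_threshold < self.high_threshold:
            raise ValueError(
                f"threshold ordering violated: need 0 < low ({self.low_threshold}) "
                f"< high ({self.high_threshold})"
            )
        if self.min_consecutive_active < 1:
            raise ValueError("min_consecutive_active must be >= 1")
        if self.window_days < 1:
            raise ValueError("window_days must be >= 1")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.active_day_cutoff < 0:
            raise ValueError("active_day_cutoff must be non-negative")
        for c in self.checkpoints:
            if not 1 <= c <= self.horizon:
                raise ValueError(f"checkpoint {c} outside [1, {self.horizon}]")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        numeric = {
            "active_day_cutoff", "min_consecutive_active", "low_threshold",
            "high_threshold", "window_days", "horizon",
        }
        kwargs: dict[str, Any] = {}
        for key, value in data.items():
            if key in numeric and not isinstance(value, (int, float)):
                raise ValueError(f"config key {key!r} must be numeric, got {value!r}")
            if key == "checkpoints":
                if not isinstance(value, (list, tuple)) or not all(
                    isinstance(v, (int, float)) for v in value
                ):
                    raise ValueError("checkpoints must be a list of study days")
                value = tuple(int(v) for v in value)
            kwargs[key] = value
        return cls(**kwargs)

    def to_dict(self) -> dict[str, Any]:
        out = dataclasses.asdict(self)
        out["checkpoints"] = list(self.checkpoints)
        return out


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML file.

    Missing keys take their defaults; an empty file yields the default
    configuration. Invariant violations (e.g. low/high threshold ordering)
    raise ``ValueError``.
    """
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ValueError(f"config file {path} does not contain a key-value mapping")
    return AnalysisConfig.from_dict(data)


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    """Write a config as YAML; ``load_config`` round-trips it exactly."""
    Path(path).write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True), encoding="utf-8"
    )
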