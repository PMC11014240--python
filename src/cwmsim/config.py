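"""Run configuration: validated, seedable, serializable."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from cwmsim.segments import SEGMENT_RANGES
from cwmsim.timing import TIMING_RANGES, VELOCITY_RANGES, resolve_ranges


class ConfigError(ValueError):
    """Configuration file or option failed validation."""


AMPLITUDE_RANGE = (0.5, 1.1)  # mm
HRV_SIGMA_RANGE = (-0.015, 0.015)
SIGN_CONVENTIONS = ("inward_negative", "inward_positive")
RETIME_MODES = ("resample", "random_edit")


@dataclass
class SimulationConfig:
    """Everything needed to regenerate a recording bit-for-bit.

    Exactly one of ``n_cycles`` / ``duration`` must be set.  ``snr_db``
    may be None (no noise); ``amplitude_mm`` may be None (sampled from
    [0.5, 1.1] mm per run).
    """

    seed: int | None = None
    fs: float = 100.0
    n_cycles: int | None = None
    duration: float | None = None
    snr_db: float | None = 10.0
    amplitude_mm: float | None = None
    hrv_sigma_range: tuple[float, float] = HRV_SIGMA_RANGE
    detrend_order: int = 3
    sign_convention: str = "inward_negative"
    retime: str = "resample"
    timing: dict = field(default_factory=dict)
    velocity: dict = field(default_factory=dict)
    segments: dict = field(default_factory=dict)

    def validate(self, require_seed: bool = False) -> None:
        if require_seed and self.seed is None:
            raise ConfigError("seed: a seed is mandatory (no silent entropy)")
        if self.fs <= 0:
            raise ConfigError(f"fs: must be positive, got {self.fs}")
        if self.n_cycles is not None and self.duration is not None:
            raise ConfigError("n_cycles/duration: set at most one")
        if self.n_cycles is not None and self.n_cycles < 1:
            raise ConfigError(f"n_cycles: must be >= 1, got {self.n_cycles}")
        if self.duration is not None and self.duration <= 0:
            raise ConfigError(f"duration: must be positive, got {self.duration}")
        if self.detrend_order < 0:
            raise ConfigError(f"detrend_order: must be >= 0, got {self.detrend_order}")
        if self.sign_convention not in SIGN_CONVENTIONS:
            raise ConfigError(
                f"sign_convention: {self.sign_convention!r} not in {SIGN_CONVENTIONS}")
        if self.retime not in RETIME_MODES:
            raise ConfigError(f"retime: {self.retime!r} not in {RETIME_MODES}")
        if self.amplitude_mm is not None and not (
                AMPLITUDE_RANGE[0] <= self.amplitude_mm <= AMPLITUDE_RANGE[1]):
            raise ConfigError(
                f"amplitude_mm: {self.amplitude_mm} outside bound {list(AMPLITUDE_RANGE)}")
        lo, hi = self.hrv_sigma_range
        if not (HRV_SIGMA_RANGE[0] - 1e-12 <= lo <= hi <= HRV_SIGMA_RANGE[1] + 1e-12):
            raise ConfigError(
                f"hrv_sigma_range: {self.hrv_sigma_range} outside bound {list(HRV_SIGMA_RANGE)}")
        for section, defaults in (("timing", TIMING_RANGES),
                                  ("velocity", VELOCITY_RANGES),
                                  ("segments", SEGMENT_RANGES)):
            try:
                resolve_ranges(defaults, getattr(self, section))
            except ValueError as exc:
                raise ConfigError(f"{section}: {exc}") from exc

    def resolved_ranges(self) -> dict[str, dict[str, tuple[float, float]]]:
        """Default parameter tables with this config's overrides applied."""
        return {
            "timing": resolve_ranges(TIMING_RANGES, self.timing),
            "velocity": resolve_ranges(VELOCITY_RANGES, self.velocity),
            "segments": resolve_ranges(SEGMENT_RANGES, self.segments),
        }

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hrv_sigma_range"] = list(self.hrv_sigma_range)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(
                f"unknown config key(s): {sorted(unknown)}; known: {sorted(known)}")
        kwargs = dict(data)
        if "hrv_sigma_range" in kwargs and kwargs["hrv_sigma_range"] is not None:
            kwargs["hrv_sigma_range"] = tuple(kwargs["hrv_sigma_range"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


def load_config(path: str | Path) -> SimulationConfig:
    """Load and validate a YAML configuration file.

    An empty file yields the all-defaults config; unknown keys and
    out-of-range overrides raise ConfigError naming the offending key.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config file {path}: {exc}") from exc
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return SimulationConfig.from_dict(data)


def save_config(cfg: SimulationConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
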