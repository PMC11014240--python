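"""Uniformly sampled 1-D signal container shared by all modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: (cycle index, marker name, time in seconds from trace start)
Fiducial = tuple[int, str, float]


@dataclass
class Trace:
    """A uniformly sampled single-channel signal.

    Parameters
    ----------
    samples
        Signal values, one per sample.
    fs
        Sampling rate in Hz.
    units
        ``"velocity"`` or ``"displacement"``.
    scale
        ``"normalized"`` (model units) or ``"mm"``.
    cycle_bounds
        Sample indices of cycle starts, plus the one-past-the-end index.
    fiducials
        Per-cycle landmark annotations as (cycle, marker, time_s).
    meta
        Free-form provenance (resolved config, per-cycle parameters, ...).
    """

    samples: np.ndarray
    fs: float
    units: str = "velocity"
    scale: str = "normalized"
    cycle_bounds: list[int] = field(default_factory=list)
    fiducials: list[Fiducial] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.cycle_bounds:
            bounds = list(self.cycle_bounds)
            if bounds != sorted(bounds):
                raise ValueError("cycle_bounds must be sorted")
            if bounds[-1] > self.samples.size:
                raise ValueError("cycle_bounds exceed trace length")

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds from trace start."""
        return np.arange(self.n) / self.fs

    def copy_with(self, samples: np.ndarray, **overrides) -> "Trace":
        """New trace with replaced samples, inheriting remaining attributes."""
        kwargs = dict(
            fs=self.fs,
            units=self.units,
            scale=self.scale,
            cycle_bounds=list(self.cycle_bounds),
            fiducials=list(self.fiducials),
            meta=dict(self.meta),
        )
        kwargs.update(overrides)
        return Trace(samples=np.asarray(samples, dtype=float), **kwargs)
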