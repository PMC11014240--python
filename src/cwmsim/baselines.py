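"""Three published comparison models for heartbeat chest-wall motion.

All three accept the same cycle-length inputs as the primary simulator so
model-vs-model comparisons are a single call:

* a van der Pol relaxation oscillator,
* a Gaussian pulse train,
* an "improved" Gaussian pulse model (modulated-Gaussian acceleration,
  double-integrated to displacement).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from cwmsim.trace import Trace


@dataclass
class VdpParams:
    """van der Pol oscillator x'' - alpha (1 - x^2) x' + omega^2 x = 0."""

    alpha: float = 1.0
    omega: float = 2.0 * math.pi / 0.82
    init: tuple[float, float] = (0.0, 1.0)
    fs: float = 100.0
    duration: float = 8.0

    def __post_init__(self):
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @classmethod
    def from_cycle_lengths(cls, cycle_lens, fs: float = 100.0, alpha: float = 1.0,
                           duration: float | None = None) -> "VdpParams":
        cycle_lens = np.asarray(cycle_lens, dtype=float)
        if duration is None:
            duration = float(cycle_lens.sum())
        return cls(alpha=alpha, omega=2.0 * math.pi / float(cycle_lens.mean()),
                   fs=fs, duration=duration)


def vdp_waveform(p: VdpParams) -> Trace:
    """Integrate the oscillator with fixed-step RK4 at step 1/fs."""
    n = int(round(p.duration * p.fs))
    h = 1.0 / p.fs
    alpha, omega2 = p.alpha, p.omega**2

    def deriv(state):
        x, v = state
        return np.array([v, alpha * (1.0 - x * x) * v - omega2 * x])

    state = np.array(p.init, dtype=float)
    xs = np.empty(n)
    for i in range(n):
        xs[i] = state[0]
        k1 = deriv(state)
        k2 = deriv(state + 0.5 * h * k1)
        k3 = deriv(state + 0.5 * h * k2)
        k4 = deriv(state + h * k3)
        state = state + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.all(np.isfinite(state)):
            raise RuntimeError(f"van der Pol integration diverged at step {i}")
    return Trace(samples=xs, fs=p.fs, units="displacement", scale="normalized",
                 meta={"model": "vdp", "alpha": p.alpha, "omega": p.omega})


@dataclass
class PulseTrainParams:
    """Sum of Gaussians x(t) = sum_n a exp(-(t - T_n)^2 / (2 c^2)).

    ``times`` are absolute pulse instants in seconds, strictly increasing.
    """

    a: float = 0.2
    c: float = 0.1
    times: np.ndarray = field(default_factory=lambda: np.array([1.0]))

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError("pulse width c must be positive")
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("pulse times must be strictly increasing")

    @classmethod
    def from_cycle_lengths(cls, cycle_lens, a: float = 0.2, c: float = 0.1
                           ) -> "PulseTrainParams":
        return cls(a=a, c=c, times=np.cumsum(np.asarray(cycle_lens, dtype=float)))


def gaussian_pulse_train(p: PulseTrainParams, duration: float, fs: float) -> Trace:
    t = np.arange(int(round(duration * fs))) / fs
    x = np.zeros_like(t)
    for tn in p.times:
        x += p.a * np.exp(-((t - tn) ** 2) / (2.0 * p.c**2))
    return Trace(samples=x, fs=fs, units="displacement", scale="normalized",
                 meta={"model": "pulse_train", "a": p.a, "c": p.c})


@dataclass
class ImprovedGaussParams:
    """Modulated-Gaussian per-cycle acceleration, double-integrated.

    Per cycle, on the sample-index axis i: a(i) = g(i) exp(-(i-b)^2/c) with
    g(i) = eta cos(omega i + gamma sin(Omega i)).  The published constants
    put b on a sample-index scale; override ``b``/``c`` for other rates.
    """

    b: float = 50.0
    c: float = 0.015
    omega: float = 0.2
    gamma: float = 0.1
    big_omega: float = 0.3
    eta: float = 0.5
    cycle_lens: np.ndarray = field(default_factory=lambda: np.array([0.82]))

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError("c must be positive")
        self.cycle_lens = np.asarray(self.cycle_lens, dtype=float)
        if np.any(self.cycle_lens <= 0):
            raise ValueError("cycle lengths must be positive")

    @classmethod
    def from_cycle_lengths(cls, cycle_lens, **kwargs) -> "ImprovedGaussParams":
        return cls(cycle_lens=np.asarray(cycle_lens, dtype=float), **kwargs)


def improved_gauss_modulation(t: np.ndarray, p: ImprovedGaussParams) -> np.ndarray:
    """g(t) = eta cos(omega t + gamma sin(Omega t))."""
    return p.eta * np.cos(p.omega * t + p.gamma * np.sin(p.big_omega * t))


def improved_gauss_acceleration(p: ImprovedGaussParams, fs: float) -> Trace:
    """Concatenated per-cycle acceleration profiles."""
    chunks = []
    bounds = [0]
    for cl in p.cycle_lens:
        i = np.arange(int(round(cl * fs)), dtype=float)
        chunks.append(improved_gauss_modulation(i, p) * np.exp(-((i - p.b) ** 2) / p.c))
        bounds.append(bounds[-1] + i.size)
    return Trace(samples=np.concatenate(chunks), fs=fs, units="acceleration",
                 scale="normalized", cycle_bounds=bounds,
                 meta={"model": "improved_gauss"})


def _linear_detrend(x: np.ndarray, t: np.ndarray) -> np.ndarray:
    coeffs = np.polynomial.polynomial.polyfit(t, x, 1)
    return x - np.polynomial.polynomial.polyval(t, coeffs)


def improved_gaussian_displacement(p: ImprovedGaussParams, fs: float) -> Trace:
    """Double-integrate the acceleration, linearly detrending each pass.

    Without the detrend the second integral diverges quadratically.
    """
    acc = improved_gauss_acceleration(p, fs)
    t = acc.times
    vel = _linear_detrend(
        cumulative_trapezoid(acc.samples, dx=1.0 / fs, initial=0.0), t)
    disp = _linear_detrend(cumulative_trapezoid(vel, dx=1.0 / fs, initial=0.0), t)
    return acc.copy_with(disp, units="displacement")
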