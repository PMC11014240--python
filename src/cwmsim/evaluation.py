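"""Similarity metrics and spectral tools for comparing motion traces."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cwmsim.trace import Trace

try:  # optional acceleration; the pure-numpy path is the reference
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _dtw_core(a: np.ndarray, b: np.ndarray) -> float:
    # Full DP, absolute-difference local cost, two-row memory.
    n, m = a.size, b.size
    prev = np.empty(m)
    cur = np.empty(m)
    prev[0] = abs(a[0] - b[0])
    for j in range(1, m):
        prev[j] = prev[j - 1] + abs(a[0] - b[j])
    for i in range(1, n):
        cur[0] = prev[0] + abs(a[i] - b[0])
        for j in range(1, m):
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = best + abs(a[i] - b[j])
        prev, cur = cur, prev
    return float(prev[m - 1])


if _HAVE_NUMBA:
    _dtw_core = _njit(cache=False)(_dtw_core)


def dtw_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Dynamic-time-warping distance, unconstrained full dynamic program.

    D(i,j) = |a_i - b_j| + min(D(i-1,j-1), D(i-1,j), D(i,j-1)) with
    D(1,1) = |a_1 - b_1|; returns D(len a, len b).
    """
    a = np.ascontiguousarray(a, dtype=float)
    b = np.ascontiguousarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("dtw_distance requires non-empty inputs")
    return _dtw_core(a, b)


def rmse(s: np.ndarray, x: np.ndarray) -> float:
    """Root-mean-squared error between two equal-length signals."""
    s = np.asarray(s, dtype=float)
    x = np.asarray(x, dtype=float)
    if s.size == 0:
        raise ValueError("rmse requires non-empty inputs")
    if s.shape != x.shape:
        raise ValueError(f"length mismatch: {s.shape} vs {x.shape}")
    return float(np.sqrt(np.mean((s - x) ** 2)))


def minmax_normalize(x: np.ndarray) -> np.ndarray:
    """Map an array onto [0, 1]; constant input maps to all zeros."""
    x = np.asarray(x, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


@dataclass(frozen=True)
class DistanceReport:
    metric: str
    value: float
    window_offset: int = 0
    n_realizations: int = 1

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("distance must be non-negative")
        if self.window_offset < 0:
            raise ValueError("window offset must be non-negative")


def sliding_window_min_distance(
    sim: Trace,
    ref: Trace,
    win_s: float = 5.0,
    step: int = 2,
    metric: str = "dtw",
    normalize: bool = True,
) -> DistanceReport:
    """Best alignment of the first ``win_s`` seconds of sim against ref.

    A window of the same length slides over ref in steps of ``step``
    samples; the minimum metric value and the offset achieving it are
    returned.  Both signals are min-max normalized first unless disabled.
    """
    if sim.fs != ref.fs:
        raise ValueError(f"sampling-rate mismatch: {sim.fs} vs {ref.fs}")
    if metric not in ("dtw", "rmse"):
        raise ValueError(f"unknown metric {metric!r}")
    win = int(round(win_s * sim.fs))
    if sim.n < win or ref.n < win:
        raise ValueError(f"both traces must be at least {win_s} s long")
    a = sim.samples[:win]
    b = ref.samples
    if normalize:
        a = minmax_normalize(a)
        b = minmax_normalize(b)
    fn = dtw_distance if metric == "dtw" else rmse
    best_value = np.inf
    best_offset = 0
    for offset in range(0, ref.n - win + 1, step):
        value = fn(a, b[offset:offset + win])
        if value < best_value:
            best_value = value
            best_offset = offset
    return DistanceReport(metric=metric, value=float(best_value),
                          window_offset=best_offset)


def amplitude_spectrum(trace: Trace) -> tuple[np.ndarray, np.ndarray]:
    """Hamming-windowed one-sided amplitude spectrum.

    Returns (frequencies in Hz, magnitudes).  Magnitudes are raw
    ``|rfft|`` of the windowed signal (arbitrary units).
    """
    if trace.n < 8:
        raise ValueError("need at least 8 samples for a spectrum")
    window = np.hamming(trace.n)
    spectrum = np.abs(np.fft.rfft(trace.samples * window))
    freqs = np.fft.rfftfreq(trace.n, d=1.0 / trace.fs)
    return freqs, spectrum


def spectral_peak(trace: Trace, f_min: float = 0.1) -> float:
    """Frequency of the largest spectral magnitude above ``f_min`` Hz."""
    freqs, mags = amplitude_spectrum(trace)
    keep = freqs >= f_min
    return float(freqs[keep][np.argmax(mags[keep])])


def averaged_model_distance(
    model_generator,
    ref: Trace,
    n: int = 5,
    metric: str = "dtw",
    rng: np.random.Generator | None = None,
    win_s: float = 5.0,
    step: int = 2,
    normalize: bool = True,
) -> DistanceReport:
    """Mean best-window distance over ``n`` generated realizations.

    ``model_generator(rng) -> Trace`` produces one realization; the same
    rng is threaded through all calls so the run is reproducible from one
    seed.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if rng is None:
        rng = np.random.default_rng(0)
    values = []
    for _ in range(n):
        sim = model_generator(rng)
        report = sliding_window_min_distance(sim, ref, win_s=win_s, step=step,
                                             metric=metric, normalize=normalize)
        values.append(report.value)
    return DistanceReport(metric=metric, value=float(np.mean(values)),
                          n_realizations=n)
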