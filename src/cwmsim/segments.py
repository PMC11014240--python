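"""Piecewise velocity synthesis for one cardiac cycle.

Ten contiguous segments (pb, bc, cj, je, ef, fg, gt, th, hk, fill) are each
evaluated from a simple shape function and affinely rescaled onto the
sampled extremal velocities of the cycle.  Rescaling each segment
independently means hard C0 continuity at junctions is not enforced; the
assembled trace records the junction jump magnitudes in its metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from cwmsim.timing import CycleTiming, KeypointSchedule, VelocityKeypoints
from cwmsim.trace import Trace

SEGMENT_NAMES = ("pb", "bc", "cj", "je", "ef", "fg", "gt", "th", "hk", "fill")

#: Default sampling ranges for segment shape parameters.
SEGMENT_RANGES: dict[str, tuple[float, float]] = {
    "theta_pb": (math.pi / 12, math.pi / 4),
    "alpha_pb": (4.0 / 3.0, 2.0),
    "beta_ef": (0.001, 0.1),
    "alpha_gt": (1.0 / 6.0, 3.0 / 5.0),
    "r_th": (1.5, 2.0),
    "mu_hk_frac": (1.0 / 3.0, 1.0),
    "sigma_hk": (0.01, 0.2),
    "gamma_hk": (-0.5, 0.2),
    "fill_var_frac": (0.3, 0.7),
}

#: Hard clip on the filling-segment Rayleigh variance, seconds^2.
FILL_VAR_CLIP = (0.03, 0.06)

#: Sigmoid saturation levels fixing the bc and fg steepness.
BC_SATURATION = 0.9
FG_SATURATION = 0.99

#: Decay target fixing the cj rate ("decreases to 0.01").
CJ_TARGET = 0.01


class SegmentTooShortError(ValueError):
    """A segment received fewer than two samples (sampling rate too low)."""


def _grid(L: float, fs: float, t: np.ndarray | None) -> np.ndarray:
    if t is not None:
        return np.asarray(t, dtype=float)
    if L <= 0:
        raise ValueError(f"segment length must be positive, got {L}")
    n = int(round(L * fs))
    if n < 2:
        raise SegmentTooShortError(
            f"only {n} sample(s) fit in a {L:.4f} s segment at fs={fs} Hz"
        )
    return np.arange(n) / fs


def rescale_to_interval(samples: np.ndarray, v_min: float, v_max: float) -> np.ndarray:
    """Affinely map an array so its minimum hits v_min and maximum v_max.

    Order-preserving.  A constant array maps to the interval midpoint.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("cannot rescale an empty array")
    if v_max < v_min:
        raise ValueError(f"v_max < v_min: {(v_min, v_max)}")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.full_like(x, 0.5 * (v_min + v_max))
    return v_min + (x - lo) * (v_max - v_min) / (hi - lo)


def seg_sinusoid_pb(L: float, fs: float, theta: float, alpha: float,
                    t: np.ndarray | None = None) -> np.ndarray:
    """PQ-interval sinusoid: sin(2*pi*t/(alpha*L) + theta)."""
    t = _grid(L, fs, t)
    return np.sin(2.0 * math.pi * t / (alpha * L) + theta)


def logistic_rate(L: float, saturation: float) -> float:
    """Steepness k with 1/(1+exp(-k*L/2)) = saturation."""
    if not 0.5 < saturation < 1.0:
        raise ValueError("saturation must be in (0.5, 1)")
    return 2.0 * math.log(saturation / (1.0 - saturation)) / L


def seg_logistic(L: float, fs: float, saturation: float,
                 t: np.ndarray | None = None) -> np.ndarray:
    """Rising sigmoid centered at L/2, reaching ``saturation`` at t=L."""
    if L <= 0:
        raise ValueError(f"segment length must be positive, got {L}")
    t = _grid(L, fs, t)
    k = logistic_rate(L, saturation)
    return 1.0 / (1.0 + np.exp(-k * (t - 0.5 * L)))


def seg_exp_decay(L: float, fs: float, target: float,
                  t: np.ndarray | None = None) -> np.ndarray:
    """Exponential decay from 1 at t=0 to ``target`` at t=L."""
    if L <= 0:
        raise ValueError(f"segment length must be positive, got {L}")
    if not 0.0 < target < 1.0:
        raise ValueError(f"decay target must be in (0, 1), got {target}")
    t = _grid(L, fs, t)
    k = -math.log(target) / L
    return np.exp(-k * t)


def seg_rayleigh(L: float, fs: float, sigma: float,
                 t: np.ndarray | None = None) -> np.ndarray:
    """Rayleigh-shaped rise/fall: (t/sigma^2) * exp(-t^2 / (2 sigma^2))."""
    if L <= 0:
        raise ValueError(f"segment length must be positive, got {L}")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    t = _grid(L, fs, t)
    return (t / sigma**2) * np.exp(-(t**2) / (2.0 * sigma**2))


def seg_cosine_gt(L: float, fs: float, alpha_gt: float,
                  t: np.ndarray | None = None) -> np.ndarray:
    """Slow cosine decay: cos(2*pi*(alpha_gt/L)*t); starts at 1."""
    if L <= 0:
        raise ValueError(f"segment length must be positive, got {L}")
    t = _grid(L, fs, t)
    return np.cos(2.0 * math.pi * (alpha_gt / L) * t)


def seg_sine_th(L: float, fs: float, r_th: float,
                t: np.ndarray | None = None) -> np.ndarray:
    """Sine with period r_th*L phase-shifted by 3*pi/2; starts at -1."""
    if L <= 0:
        raise ValueError(f"segment length must be positive, got {L}")
    t = _grid(L, fs, t)
    return np.sin(2.0 * math.pi * t / (r_th * L) + 1.5 * math.pi)


def seg_skew_gauss_hk(L: float, fs: float, mu: float, sigma: float, gamma: float,
                      t: np.ndarray | None = None) -> np.ndarray:
    """Skewed Gaussian: N(mu, sigma) density times (1 - gamma*((t-mu)/sigma)^3)."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    t = _grid(L, fs, t)
    z = (t - mu) / sigma
    return (1.0 / math.sqrt(2.0 * math.pi * sigma**2)) * np.exp(-0.5 * z**2) * (1.0 - gamma * z**3)


@dataclass(frozen=True)
class SegmentParams:
    """Shape parameters for the ten segments of one cycle.

    mu_hk is in hk-segment-local time (offset from point h); sigma_fill is
    the Rayleigh standard deviation of the filling segment.
    """

    theta_pb: float
    alpha_pb: float
    beta_ef: float
    alpha_gt: float
    r_th: float
    mu_hk: float
    sigma_hk: float
    gamma_hk: float
    sigma_fill: float


def sample_segment_params(
    rng: np.random.Generator,
    timing: CycleTiming,
    schedule: KeypointSchedule,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> SegmentParams:
    """Draw the shape parameters of every segment for one cycle."""
    r = ranges if ranges is not None else SEGMENT_RANGES

    def u(key: str) -> float:
        lo, hi = r[key]
        return lo if lo == hi else float(rng.uniform(lo, hi))

    # hk peak sits inside the IVR period; express it in segment-local time.
    mu_hk = (schedule.t_end - schedule.h) + u("mu_hk_frac") * timing.l_ivr
    var_fill = float(np.clip(u("fill_var_frac") * timing.l_rpf, *FILL_VAR_CLIP))
    return SegmentParams(
        theta_pb=u("theta_pb"),
        alpha_pb=u("alpha_pb"),
        beta_ef=u("beta_ef"),
        alpha_gt=u("alpha_gt"),
        r_th=u("r_th"),
        mu_hk=mu_hk,
        sigma_hk=u("sigma_hk"),
        gamma_hk=u("gamma_hk"),
        sigma_fill=math.sqrt(var_fill),
    )


def synthesize_cycle_velocity(
    timing: CycleTiming,
    schedule: KeypointSchedule,
    vk: VelocityKeypoints,
    params: SegmentParams,
    fs: float,
) -> Trace:
    """Assemble the full-cycle velocity trace from the ten segments.

    The cycle is sampled on a uniform grid of round(cycle_len*fs) points;
    segment boundaries are snapped to sample indices so the segments tile
    the grid with no gaps or overlaps.
    """
    if fs < 50:
        raise ValueError(f"fs must be at least 50 Hz, got {fs}")
    n_total = int(round(timing.cycle_len * fs))
    bounds_t = schedule.segment_boundaries()
    idx = [int(round(tb * fs)) for tb in bounds_t]
    idx[0], idx[-1] = 0, n_total

    for m, name in enumerate(SEGMENT_NAMES):
        if idx[m + 1] - idx[m] < 2:
            raise SegmentTooShortError(
                f"segment {name!r} gets {idx[m + 1] - idx[m]} sample(s) at fs={fs} Hz"
            )

    def local_t(m: int) -> np.ndarray:
        return np.arange(idx[m], idx[m + 1]) / fs - bounds_t[m]

    lengths = [bounds_t[m + 1] - bounds_t[m] for m in range(10)]

    shapes = [
        seg_sinusoid_pb(lengths[0], fs, params.theta_pb, params.alpha_pb, t=local_t(0)),
        seg_logistic(lengths[1], fs, BC_SATURATION, t=local_t(1)),
        seg_exp_decay(lengths[2], fs, CJ_TARGET, t=local_t(2)),
        seg_rayleigh(lengths[3], fs, timing.l_je, t=local_t(3)),
        seg_exp_decay(lengths[4], fs, params.beta_ef, t=local_t(4)),
        seg_logistic(lengths[5], fs, FG_SATURATION, t=local_t(5)),
        seg_cosine_gt(lengths[6], fs, params.alpha_gt, t=local_t(6)),
        seg_sine_th(lengths[7], fs, params.r_th, t=local_t(7)),
        seg_skew_gauss_hk(lengths[8], fs, params.mu_hk, params.sigma_hk,
                          params.gamma_hk, t=local_t(8)),
        seg_rayleigh(lengths[9], fs, params.sigma_fill, t=local_t(9)),
    ]

    fg = rescale_to_interval(shapes[5], vk.v_f, vk.v_g)
    intervals = [
        (vk.v_b, vk.v_afp),       # pb
        (vk.v_b, vk.v_aop),       # bc
        (vk.v_j, vk.v_aop),       # cj
        (vk.v_j, vk.v_e),         # je
        (vk.v_f, vk.v_e),         # ef
        (vk.v_f, vk.v_g),         # fg
        (vk.v_t, float(fg[-1])),  # gt: anchored to the fg endpoint
        (vk.v_t, vk.v_h),         # th
        (vk.v_ivrv, vk.v_ivrp),   # hk
        (0.0, vk.v_rpf),          # fill
    ]
    segments = [rescale_to_interval(shape, lo, hi)
                for shape, (lo, hi) in zip(shapes, intervals)]
    segments[5] = fg

    samples = np.concatenate(segments)
    junction_jumps = [float(abs(segments[m + 1][0] - segments[m][-1])) for m in range(9)]
    fiducials = [(0, name, float(tv)) for name, tv in zip(
        ("p_peak", "b", "c", "s", "j", "e", "f", "g", "t", "h", "k",
         "t_peak", "t_end", "cycle_end"),
        (schedule.p_peak, schedule.b, schedule.c, schedule.s, schedule.j,
         schedule.e, schedule.f, schedule.g, schedule.t, schedule.h,
         schedule.k, schedule.t_peak, schedule.t_end, schedule.cycle_end),
    )]
    return Trace(
        samples=samples, fs=fs, units="velocity", scale="normalized",
        cycle_bounds=[0, n_total], fiducials=fiducials,
        meta={
            "cycle_len": timing.cycle_len,
            "segment_index": dict(zip(SEGMENT_NAMES, zip(idx[:-1], idx[1:]))),
            "junction_jumps": junction_jumps,
        },
    )
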