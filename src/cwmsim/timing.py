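"""Cardiac-cycle timing: phase durations, landmark times, extremal velocities.

One simulated beat is laid out on a timeline that starts at the P-wave peak
(atrial-systole onset).  Atrial systole occupies ``[0, L_asys]``, systole
``[L_asys, L_asys + L_sys]``, and diastole (IVR, rapid filling, reduced
filling) fills the remainder of the cycle.  All durations are in seconds,
velocities in normalized m/s-scale model units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from cwmsim.rng import MAX_REDRAWS

#: Maximum allowed QRS-complex duration, seconds.
QRS_CAP = 0.120

#: Default sampling ranges/constants for durations and landmark placement.
TIMING_RANGES: dict[str, tuple[float, float]] = {
    "cycle_len": (0.58, 1.07),
    "cycle_len_mean": (0.82, 0.82),
    "cycle_len_sd": (0.08, 0.08),
    "r_sys_dia": (0.7, 0.9),
    "r_ivc": (0.09, 0.13),
    "qrs_over_ivc": (1.8, 2.5),
    "l_sj": (0.01, 0.03),
    "l_st": (0.07, 0.09),
    "r_ivr": (0.09, 0.13),
    "r_asys": (0.16, 0.22),
    "r_rpf": (0.25, 0.40),
    "l_je": (0.02, 0.03),
    "g_frac": (0.2, 0.3),
    "t_frac": (0.4, 0.6),
    "h_frac": (0.75, 1.0),
}

#: Default sampling ranges for extremal velocities (model units).
VELOCITY_RANGES: dict[str, tuple[float, float]] = {
    "v_rpfp": (0.02, 0.08),
    "afp_frac": (0.2, 0.5),
    "v_b": (-0.02, 0.02),
    "v_aop": (-0.01, 0.02),
    "v_rpe": (0.04, 0.14),
    "j_frac": (0.1, 0.7),
    "v_e_hi": (0.1, 0.1),
    "f_frac": (0.5, 1.0),
    "v_g_hi": (0.01, 0.01),
    "vt_frac": (0.1, 0.5),
    "v_h": (-0.001, 0.005),
    "v_ivrp": (0.01, 0.02),
    "v_ivrv": (-0.01, 0.0),
    "v_rpf": (0.02, 0.08),
}


def resolve_ranges(
    defaults: dict[str, tuple[float, float]],
    overrides: dict[str, object] | None,
) -> dict[str, tuple[float, float]]:
    """Merge user overrides into a default range table.

    An override may be a (lo, hi) pair or a single number (degenerate
    range).  Overrides must name known parameters and stay within the
    documented default interval; violations raise ValueError naming the
    offending key and its bound.
    """
    resolved = dict(defaults)
    if not overrides:
        return resolved
    for key, value in overrides.items():
        if key not in defaults:
            raise ValueError(f"unknown parameter {key!r}; known: {sorted(defaults)}")
        if isinstance(value, (int, float)):
            lo = hi = float(value)
        else:
            try:
                lo, hi = (float(v) for v in value)
            except (TypeError, ValueError) as exc:
                raise ValueError(f"override for {key!r} must be a number or (lo, hi) pair") from exc
        if lo > hi:
            raise ValueError(f"override for {key!r} has lo > hi: {(lo, hi)}")
        dlo, dhi = defaults[key]
        if lo < dlo - 1e-12 or hi > dhi + 1e-12:
            raise ValueError(
                f"override for {key!r} = {(lo, hi)} outside the documented bound [{dlo}, {dhi}]"
            )
        resolved[key] = (lo, hi)
    return resolved


def _uniform(rng: np.random.Generator, bounds: tuple[float, float]) -> float:
    lo, hi = bounds
    if lo == hi:
        return lo
    return float(rng.uniform(lo, hi))


@dataclass(frozen=True)
class CycleTiming:
    """Durations of every phase of one cardiac cycle, seconds."""

    cycle_len: float
    r_sys_dia: float
    l_sys: float
    l_dia: float
    l_ivc: float
    l_qrs: float
    l_sj: float
    l_st: float
    l_ivr: float
    l_asys: float
    l_rpf: float
    l_rdf: float
    l_pb: float
    l_twave: float
    l_je: float

    def validate(self) -> None:
        """Raise ValueError if any duration invariant is violated."""
        durations = {
            "l_sys": self.l_sys, "l_dia": self.l_dia, "l_ivc": self.l_ivc,
            "l_qrs": self.l_qrs, "l_sj": self.l_sj, "l_st": self.l_st,
            "l_ivr": self.l_ivr, "l_asys": self.l_asys, "l_rpf": self.l_rpf,
            "l_rdf": self.l_rdf, "l_pb": self.l_pb, "l_twave": self.l_twave,
            "l_je": self.l_je,
        }
        for name, value in durations.items():
            if not value > 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.l_qrs > QRS_CAP + 1e-12:
            raise ValueError(f"l_qrs exceeds {QRS_CAP*1000:.0f} ms: {self.l_qrs}")
        if not self.l_ivc < self.l_qrs <= 2.5 * self.l_ivc + 1e-12:
            raise ValueError("l_qrs must lie in (l_ivc, 2.5*l_ivc]")
        if abs(self.l_sys + self.l_dia - self.cycle_len) > 1e-9:
            raise ValueError("l_sys + l_dia must equal cycle_len")
        if abs(self.l_ivr + self.l_rpf + self.l_rdf + self.l_asys - self.l_dia) > 1e-9:
            raise ValueError("diastolic sub-phases must sum to l_dia")
        if abs(self.l_pb - (self.l_asys - (self.l_qrs - self.l_ivc))) > 1e-9:
            raise ValueError("l_pb must equal l_asys - (l_qrs - l_ivc)")
        if abs(self.l_twave - (self.l_sys - self.l_ivc - self.l_sj - self.l_st)) > 1e-9:
            raise ValueError("l_twave must equal l_sys - l_ivc - l_sj - l_st")


@dataclass(frozen=True)
class KeypointSchedule:
    """Within-cycle times (seconds from the P-wave peak) of landmark points."""

    p_peak: float  # always 0.0
    b: float       # ~Q-wave, end of PQ interval
    c: float       # IVC local maximum, inside the RS interval
    s: float       # S-wave
    j: float       # J-point
    e: float       # post-J local peak
    f: float       # T-wave onset (first ejection minimum)
    g: float       # pre-T-peak local maximum
    t: float       # near-T-peak minimum
    h: float       # end-systolic settling point
    k: float       # diastolic valley (may fall inside filling)
    cycle_end: float
    t_peak: float  # derived: midway through the T-wave
    t_end: float   # derived: end of the T-wave (= end of systole)

    def ordered_times(self) -> list[float]:
        return [self.p_peak, self.b, self.c, self.s, self.j, self.e,
                self.f, self.g, self.t, self.h, self.k, self.cycle_end]

    def validate(self) -> None:
        times = self.ordered_times()
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"keypoint times must be strictly increasing: {times}")

    def segment_boundaries(self) -> list[float]:
        """Boundaries of the ten velocity segments pb..fill."""
        return [self.p_peak, self.b, self.c, self.j, self.e, self.f,
                self.g, self.t, self.h, self.k, self.cycle_end]


@dataclass(frozen=True)
class VelocityKeypoints:
    """Sampled extremal velocities for one cycle (model units).

    ``v_rpe`` and ``v_rpfp`` are positive magnitudes; the ejection extremes
    ``v_j``, ``v_f``, ``v_t`` carry the inward-negative sign convention.
    """

    v_b: float
    v_afp: float
    v_aop: float
    v_j: float
    v_e: float
    v_f: float
    v_g: float
    v_t: float
    v_h: float
    v_ivrp: float
    v_ivrv: float
    v_rpf: float
    v_rpe: float
    v_rpfp: float


def sample_cycle_length(
    rng: np.random.Generator,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> float:
    """Draw one cardiac-cycle duration, seconds.

    Truncated Gaussian by rejection: Normal(0.82, 0.08) redrawn until it
    falls inside [0.58, 1.07] (56-102 bpm, floored to two decimals).
    """
    r = ranges if ranges is not None else TIMING_RANGES
    lo, hi = r["cycle_len"]
    mean = r["cycle_len_mean"][0]
    sd = r["cycle_len_sd"][0]
    for _ in range(MAX_REDRAWS):
        value = float(rng.normal(mean, sd))
        if lo <= value <= hi:
            return value
    raise RuntimeError("cycle-length rejection sampling failed; check overrides")


def sample_phase_durations(
    rng: np.random.Generator,
    cycle_len: float,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> CycleTiming:
    """Sample the duration of every phase of a cycle of length ``cycle_len``.

    The whole draw is rejected and repeated until atrial systole outlasts
    the QRS complex (required so the PQ interval stays positive); the
    derived reduced-filling duration subtracts all three other diastolic
    sub-phases so the diastole closes exactly.
    """
    r = ranges if ranges is not None else TIMING_RANGES
    for _ in range(MAX_REDRAWS):
        ratio = _uniform(rng, r["r_sys_dia"])
        l_dia = cycle_len / (1.0 + ratio)
        l_sys = ratio * cycle_len / (1.0 + ratio)
        l_ivc = _uniform(rng, r["r_ivc"]) * l_sys
        l_qrs = min(_uniform(rng, r["qrs_over_ivc"]) * l_ivc, QRS_CAP)
        l_sj = _uniform(rng, r["l_sj"])
        l_st = _uniform(rng, r["l_st"])
        l_ivr = _uniform(rng, r["r_ivr"]) * l_dia
        l_asys = _uniform(rng, r["r_asys"]) * l_dia
        l_rpf = _uniform(rng, r["r_rpf"]) * l_dia
        l_je = _uniform(rng, r["l_je"])
        if l_asys <= l_qrs:
            continue
        l_rdf = l_dia - l_ivr - l_rpf - l_asys
        l_pb = l_asys - (l_qrs - l_ivc)
        l_twave = l_sys - l_ivc - l_sj - l_st
        if min(l_rdf, l_pb, l_twave) <= 0:
            continue
        timing = CycleTiming(
            cycle_len=cycle_len, r_sys_dia=ratio, l_sys=l_sys, l_dia=l_dia,
            l_ivc=l_ivc, l_qrs=l_qrs, l_sj=l_sj, l_st=l_st, l_ivr=l_ivr,
            l_asys=l_asys, l_rpf=l_rpf, l_rdf=l_rdf, l_pb=l_pb,
            l_twave=l_twave, l_je=l_je,
        )
        timing.validate()
        return timing
    raise RuntimeError(
        "phase-duration sampling failed after bounded redraws; "
        "parameter overrides are mutually inconsistent"
    )


def place_keypoints(
    rng: np.random.Generator,
    timing: CycleTiming,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> KeypointSchedule:
    """Place the landmark points of one cycle on its timeline.

    b sits at the end of the PQ interval; the R instant is b + (l_qrs -
    l_ivc) so IVC occupies exactly the RS span, and c is uniform inside
    that span.  g, t, h are placed at sampled fractions of the T-wave; k is
    uniform over the second half of IVR through the first half of rapid
    filling.
    """
    r = ranges if ranges is not None else TIMING_RANGES
    b = timing.l_pb
    r_instant = b + (timing.l_qrs - timing.l_ivc)
    s = b + timing.l_qrs
    j = s + timing.l_sj
    e = j + timing.l_je
    f = j + timing.l_st
    t_end = f + timing.l_twave
    t_peak = f + 0.5 * timing.l_twave
    for _ in range(MAX_REDRAWS):
        c = float(rng.uniform(r_instant, s))
        g = f + _uniform(rng, r["g_frac"]) * timing.l_twave
        t = f + _uniform(rng, r["t_frac"]) * timing.l_twave
        h = f + _uniform(rng, r["h_frac"]) * timing.l_twave
        k = float(rng.uniform(t_end + 0.5 * timing.l_ivr,
                              t_end + timing.l_ivr + 0.5 * timing.l_rpf))
        schedule = KeypointSchedule(
            p_peak=0.0, b=b, c=c, s=s, j=j, e=e, f=f, g=g, t=t, h=h, k=k,
            cycle_end=timing.cycle_len, t_peak=t_peak, t_end=t_end,
        )
        try:
            schedule.validate()
        except ValueError:
            continue
        return schedule
    raise RuntimeError("keypoint placement failed to satisfy monotonicity")


def sample_velocity_keypoints(
    rng: np.random.Generator,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> VelocityKeypoints:
    """Sample the extremal velocities for one cycle.

    Ejection extremes are negative (inward motion); filling and atrial
    peaks positive.  The full draw is rejected until every segment's
    rescale interval is properly ordered (min <= max), which the source
    ranges do not guarantee on their own.
    """
    r = ranges if ranges is not None else VELOCITY_RANGES
    for _ in range(MAX_REDRAWS):
        v_rpfp = _uniform(rng, r["v_rpfp"])
        v_afp = _uniform(rng, r["afp_frac"]) * v_rpfp
        v_b = _uniform(rng, r["v_b"])
        v_aop = _uniform(rng, r["v_aop"])
        v_rpe = _uniform(rng, r["v_rpe"])
        v_j = -_uniform(rng, r["j_frac"]) * v_rpe
        v_e = float(rng.uniform(v_j, r["v_e_hi"][1]))
        v_f = -_uniform(rng, r["f_frac"]) * v_rpe
        v_g = float(rng.uniform(v_f, r["v_g_hi"][1]))
        v_t = -_uniform(rng, r["vt_frac"]) * abs(v_f)
        v_h = _uniform(rng, r["v_h"])
        v_ivrp = _uniform(rng, r["v_ivrp"])
        v_ivrv = _uniform(rng, r["v_ivrv"])
        v_rpf = _uniform(rng, r["v_rpf"])
        ordered = (
            v_b <= v_afp          # pb interval
            and v_b <= v_aop      # bc interval
            and v_j <= v_aop      # cj interval
            and v_f <= v_e        # ef interval
            and v_t <= v_g        # gt interval (fg endpoint ~ v_g)
            and v_t <= v_h        # th interval
        )
        if not ordered:
            continue
        return VelocityKeypoints(
            v_b=v_b, v_afp=v_afp, v_aop=v_aop, v_j=v_j, v_e=v_e, v_f=v_f,
            v_g=v_g, v_t=v_t, v_h=v_h, v_ivrp=v_ivrp, v_ivrv=v_ivrv,
            v_rpf=v_rpf, v_rpe=v_rpe, v_rpfp=v_rpfp,
        )
    raise RuntimeError("velocity-keypoint sampling failed; check overrides")


def heart_rate_endpoint(bpm: float) -> float:
    """Cycle length implied by a heart rate, floored to two decimals."""
    return math.floor(100.0 * 60.0 / bpm) / 100.0
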