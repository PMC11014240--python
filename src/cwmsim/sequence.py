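"""Long-recording assembly: noise, HRV retiming, integration, detrending.

Pipeline (build_long_sequence): sample cycles -> synthesize velocities ->
add noise -> retime each cycle to its beat interval -> concatenate ->
integrate to displacement -> polynomial detrend -> scale peak-to-peak to
the sampled amplitude.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import cumulative_trapezoid

from cwmsim.config import AMPLITUDE_RANGE, SimulationConfig
from cwmsim.rng import MAX_REDRAWS, child_rngs
from cwmsim.segments import (
    SegmentTooShortError,
    sample_segment_params,
    synthesize_cycle_velocity,
)
from cwmsim.timing import (
    place_keypoints,
    sample_cycle_length,
    sample_phase_durations,
    sample_velocity_keypoints,
)
from cwmsim.trace import Trace

HRV_CLIP = 0.1  # |deviation| bound, fraction of cycle length


def add_awgn(trace: Trace, snr_db: float | None, rng: np.random.Generator) -> Trace:
    """Add white Gaussian noise at the requested SNR (dB); None disables."""
    if snr_db is None:
        return trace.copy_with(trace.samples.copy())
    p_signal = float(np.mean(trace.samples**2))
    if p_signal == 0.0:
        raise ValueError("cannot set an SNR on a zero-power signal")
    p_noise = p_signal / 10.0 ** (snr_db / 10.0)
    noise = rng.normal(0.0, np.sqrt(p_noise), size=trace.n)
    return trace.copy_with(trace.samples + noise)


def sample_hrv_series(
    rng: np.random.Generator,
    n_cycles: int,
    sigma_range: tuple[float, float] = (-0.015, 0.015),
) -> np.ndarray:
    """Per-beat fractional cycle-length deviations.

    One run-level sigma is the absolute value of a uniform draw over
    ``sigma_range``; deviations are Normal(0, sigma) clipped to the
    physiological band [-0.1, 0.1].
    """
    if n_cycles < 1:
        raise ValueError(f"n_cycles must be >= 1, got {n_cycles}")
    sigma = abs(float(rng.uniform(*sigma_range)))
    if sigma == 0.0:
        return np.zeros(n_cycles)
    return np.clip(rng.normal(0.0, sigma, size=n_cycles), -HRV_CLIP, HRV_CLIP)


def retime_cycle(trace: Trace, target_samples: int,
                 mode: str = "resample",
                 rng: np.random.Generator | None = None) -> Trace:
    """Stretch or compress one cycle to exactly ``target_samples`` samples.

    ``resample`` does deterministic uniform linear interpolation (first and
    last values preserved, fiducial times rescaled proportionally);
    ``random_edit`` deletes or linearly inserts samples at random indices.
    """
    n = trace.n
    if n < 2:
        raise ValueError("cycle must have at least 2 samples")
    if target_samples < 2:
        raise ValueError(f"target_samples must be >= 2, got {target_samples}")
    if mode == "resample":
        if target_samples == n:
            out = trace.samples.copy()
        else:
            old_t = np.linspace(0.0, 1.0, n)
            new_t = np.linspace(0.0, 1.0, target_samples)
            out = np.interp(new_t, old_t, trace.samples)
    elif mode == "random_edit":
        if rng is None:
            raise ValueError("random_edit retiming needs an rng")
        out = trace.samples.copy()
        while out.size > target_samples:
            # never drop the endpoints
            drop = rng.integers(1, out.size - 1)
            out = np.delete(out, drop)
        while out.size < target_samples:
            at = int(rng.integers(1, out.size))
            out = np.insert(out, at, 0.5 * (out[at - 1] + out[at]))
    else:
        raise ValueError(f"unknown retime mode {mode!r}")
    ratio = (target_samples / trace.fs) / (n / trace.fs)
    fiducials = [(c, m, t * ratio) for c, m, t in trace.fiducials]
    return trace.copy_with(out, cycle_bounds=[0, target_samples], fiducials=fiducials)


def integrate_velocity(trace: Trace) -> Trace:
    """Cumulative trapezoidal integral of a velocity trace; starts at 0."""
    if trace.units != "velocity":
        raise ValueError(f"expected a velocity trace, got units={trace.units!r}")
    disp = cumulative_trapezoid(trace.samples, dx=1.0 / trace.fs, initial=0.0)
    return trace.copy_with(disp, units="displacement")


def detrend_poly(trace: Trace, order: int = 3) -> Trace:
    """Subtract the least-squares polynomial trend of the given order."""
    if trace.n <= order + 1:
        raise ValueError(
            f"need more than {order + 1} samples for an order-{order} detrend")
    t = trace.times
    coeffs = np.polynomial.polynomial.polyfit(t, trace.samples, order)
    trend = np.polynomial.polynomial.polyval(t, coeffs)
    return trace.copy_with(trace.samples - trend)


def _synthesize_one_cycle(rng_timing, rng_velocity, ranges, fs):
    """Draw one cycle end to end, redrawing if a segment underflows fs."""
    for _ in range(MAX_REDRAWS):
        cycle_len = sample_cycle_length(rng_timing, ranges["timing"])
        timing = sample_phase_durations(rng_timing, cycle_len, ranges["timing"])
        schedule = place_keypoints(rng_timing, timing, ranges["timing"])
        vk = sample_velocity_keypoints(rng_velocity, ranges["velocity"])
        params = sample_segment_params(rng_velocity, timing, schedule,
                                       ranges["segments"])
        try:
            vel = synthesize_cycle_velocity(timing, schedule, vk, params, fs)
        except SegmentTooShortError:
            continue
        return cycle_len, timing, vel
    raise RuntimeError("could not synthesize a cycle; fs too low for the ranges")


def build_long_sequence(config: SimulationConfig) -> Trace:
    """Generate a full displacement recording from a validated config.

    Returns a displacement trace in mm with per-cycle fiducials, cycle
    bounds at each beat onset, and the concatenated (noisy, retimed)
    velocity plus generation parameters in ``meta``.
    """
    config.validate(require_seed=True)
    if config.n_cycles is None and config.duration is None:
        raise ValueError("config must set n_cycles or duration")
    ranges = config.resolved_ranges()
    fs = config.fs
    rngs = child_rngs(config.seed, ["timing", "velocity", "noise", "hrv", "amplitude"])

    if config.n_cycles is not None:
        n_planned = config.n_cycles
    else:  # worst case: every cycle at the short end, shrunk by max HRV
        n_planned = int(np.ceil(config.duration / (0.9 * 0.58))) + 2
    hrv_dev = sample_hrv_series(rngs["hrv"], n_planned, config.hrv_sigma_range)

    chunks: list[np.ndarray] = []
    cycle_bounds: list[int] = [0]
    fiducials = []
    bbis: list[float] = []
    cycle_log: list[dict] = []
    total = 0.0
    for i in range(n_planned):
        cycle_len, timing, vel = _synthesize_one_cycle(
            rngs["timing"], rngs["velocity"], ranges, fs)
        vel = add_awgn(vel, config.snr_db, rngs["noise"])
        bbi = cycle_len * (1.0 + hrv_dev[i])
        target = max(2, int(round(bbi * fs)))
        vel = retime_cycle(vel, target, mode=config.retime, rng=rngs["noise"])
        offset = cycle_bounds[-1] / fs
        fiducials.extend((i, m, t + offset) for _, m, t in vel.fiducials)
        chunks.append(vel.samples)
        cycle_bounds.append(cycle_bounds[-1] + target)
        bbis.append(target / fs)
        cycle_log.append({"cycle_len": cycle_len, "bbi": bbi,
                          "hrv_dev": float(hrv_dev[i]),
                          "junction_jumps": vel.meta.get("junction_jumps")})
        total += target / fs
        if config.duration is not None and total >= config.duration:
            break

    velocity = np.concatenate(chunks)
    if config.sign_convention == "inward_positive":
        velocity = -velocity
    if config.duration is not None:
        n_target = int(round(config.duration * fs))
        velocity = velocity[:n_target]
        cycle_bounds = [b for b in cycle_bounds if b < n_target] + [n_target]

    vel_trace = Trace(samples=velocity, fs=fs, units="velocity",
                      scale="normalized", cycle_bounds=cycle_bounds,
                      fiducials=fiducials)
    disp = integrate_velocity(vel_trace)
    if config.detrend_order > 0:
        disp = detrend_poly(disp, config.detrend_order)

    if config.amplitude_mm is not None:
        amplitude = config.amplitude_mm
    else:
        amplitude = float(rngs["amplitude"].uniform(*AMPLITUDE_RANGE))
    x = disp.samples
    span = float(x.max() - x.min())
    if span == 0.0:
        raise RuntimeError("degenerate flat displacement; cannot scale")
    scaled = (x - x.min()) * (amplitude / span)

    return disp.copy_with(
        scaled, units="displacement", scale="mm",
        meta={
            "config": config.to_dict(),
            "amplitude_mm": amplitude,
            "bbi_s": bbis,
            "mean_bbi_s": float(np.mean(bbis)),
            "velocity": velocity,
            "cycles": cycle_log,
        },
    )
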