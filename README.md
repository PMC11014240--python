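# cwmsim

Synthetic heartbeat-induced chest-wall-motion (CWM) displacement traces, as
seen by CW radar or IR motion capture during breath-hold.

One cardiac cycle is modelled in ten contiguous phases anchored to
ECG-style landmarks (P peak, Q, RS interval, J point, T wave, IVR, rapid
filling, atrial systole). For each cycle the simulator samples phase
durations and extremal velocities from physiological ranges, evaluates a
simple shape function per phase (sinusoid, sigmoid, exponential decay,
Rayleigh, cosine, skewed Gaussian), rescales each onto its sampled
extremes, and concatenates. Long recordings add white noise at a chosen
SNR, retime every beat to an HRV-modulated beat interval, integrate the
velocity to displacement, remove the drift with a cubic polynomial fit,
and scale the result to a sampled millimetre amplitude.

The package also ships three published comparison models (van der Pol
relaxation oscillator, Gaussian pulse train, modulated-Gaussian
"improved" pulse model) and an evaluation toolkit (unconstrained DTW,
RMSE, sliding-window best-alignment matching, Hamming-windowed amplitude
spectra).

## CLI

All commands require an explicit `--seed`; a run is reproducible
bit-for-bit from its seed (the written manifest is sufficient to
regenerate a trace exactly).

```sh
# 8 s displacement recording at 100 Hz -> trace.csv + fiducials + manifest
cwmsim simulate --duration 8 --fs 100 --seed 1 --out trace.csv

# fixed number of beats, custom SNR, or no noise at all
cwmsim simulate --cycles 20 --seed 1 --snr-db 10 --out trace.csv
cwmsim simulate --cycles 20 --seed 1 --no-noise --out clean.csv

# comparison models
cwmsim baseline --model vdp --seed 1 --duration 8 --out vdp.csv
cwmsim baseline --model pulse_train --seed 1 --out pt.csv
cwmsim baseline --model improved_gauss --seed 1 --out ig.csv

# similarity between two traces (5 s window sliding in 2-sample steps)
cwmsim compare --sim sim.csv --ref ref.csv --metric dtw,rmse --window 5 --step 2

# one-sided amplitude spectrum
cwmsim spectrum --in trace.csv --out spectrum.csv
```

Traces are delimited text (`time_s, displacement_mm[, velocity]`) with a
`*.fiducials.csv` sibling (per-cycle landmark times) and a
`*.manifest.json` sidecar (fully resolved configuration).

A YAML config file can replace or complement the flags; every documented
sampling range is overridable within its documented bound:

```yaml
seed: 1
duration: 8
snr_db: 10
timing:
  cycle_len: [0.7, 0.9]
  r_sys_dia: 0.8        # scalar pins a parameter
velocity:
  v_rpe: [0.06, 0.10]
```

```sh
cwmsim simulate --config run.yaml --out trace.csv
```

## Library

```python
from cwmsim import SimulationConfig, build_long_sequence

trace = build_long_sequence(SimulationConfig(seed=1, duration=8.0))
trace.samples        # displacement, mm
trace.meta["velocity"]  # concatenated velocity (model units)
trace.fiducials      # (cycle, marker, time_s) landmark annotations
```

Lower-level pieces are exposed directly: `cwmsim.timing` (duration /
keypoint / velocity samplers), `cwmsim.segments` (the ten segment shape
functions and cycle assembly), `cwmsim.sequence` (noise, HRV, retiming,
integration, detrending), `cwmsim.baselines`, `cwmsim.evaluation`.

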