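# emowave

A tested, reusable implementation of the processing pipeline behind a
multimodal (mmWave radar + PPG + GSR) emotion-recognition dataset:
synthetic raw-data generation, radar vital-sign extraction, physiological
signal conditioning, signal-quality validation, windowed feature
extraction, self-assessment rating statistics, and a subject-dependent
SVM classification baseline.

## The problem

Frequency-modulated continuous-wave (FMCW) radar can monitor breathing
and heartbeat without any body contact. Each transmitted chirp mixes with
its echo into an intermediate-frequency tone whose frequency encodes the
target range, `f_IF = S·2R/c` (slope `S`, range `R`), and whose phase
encodes sub-wavelength displacement,

    φ(t) = 4π R(t) / λ,    Δd = λ·Δφ / 4π.

At 60 GHz (λ = 5 mm) a 1 mm chest movement shifts the phase by ~2.5 rad,
which makes sub-millimetre cardiac motion observable. The extraction
chain is:

1. **Range-FFT** along fast time → a range-time matrix (RTM) per virtual
   channel (12 channels from a 3 Tx × 4 Rx TDM array);
2. **MTI** static-clutter suppression by subtracting each range bin's
   slow-time mean;
3. **multi-bin phase fusion**: unwrap the complex argument of the K = 5
   strongest bins and combine them with amplitude-proportional weights
   `w_k = A(i_k) / Σ A(i_n)`;
4. channel averaging, first-order differencing (the "vital sign"), and
   zero-phase Butterworth band-passes: 0.1–0.5 Hz (respiration, 4th
   order) and 1.0–1.8 Hz (heartbeat, 6th order).

Around the radar core, the package conditions fingertip PPG (0.6–5 Hz
band-pass, linear detrend, 0.1 s moving average) and GSR (resistance →
conductance, 1 Hz low-pass), validates quality via band-split SNR and
radar-vs-PPG heart-rate agreement, extracts 32/28/24 features per
5-second window over the final 60 s of each trial, analyses 1–9 SAM
ratings (coefficient of variation, tie-aware Spearman ρ, valence–arousal
quadrants, threshold-5 binarization), and trains per-participant RBF-SVM
baselines with a 66-point (C, γ) grid search.

Every raw input can be produced by the built-in synthetic generators
(radar ADC cubes, PPG pulse trains, tonic + phasic GSR, SAM rating
tables), so the full chain is testable without downloading the real
recordings (Zenodo record 10.5281/zenodo.15825931, whose file formats the
I/O layer reads and writes).

## Worked example

```python
import numpy as np
from emowave import (ChestMotionModel, RadarConfig, SceneModel,
                     extract_vital_sign, phase_to_displacement,
                     range_resolution, simulate_adc_cube)
from emowave.validation import dominant_frequency

config = RadarConfig()  # the 60 GHz / 12-virtual-channel study setup
print(f"range resolution: {range_resolution(config):.4f} m")

scene = SceneModel(
    target=ChestMotionModel(resp_rate=0.25, heart_rate=1.2),
    clutter=((1.3, 0.8),),  # a static wall reflection
    noise_sd=0.1, seed=7,
)
cube = simulate_adc_cube(config, scene, duration=60.0)
bundle = extract_vital_sign(cube, config)

resp = dominant_frequency(bundle.respiration, bundle.slow_time_rate, (0.1, 0.5))
heart = dominant_frequency(bundle.heartbeat, bundle.slow_time_rate, (0.8, 2.0))
print(f"respiration: {resp:.3f} Hz (truth 0.250)")
print(f"heart rate:  {heart * 60:.1f} bpm (truth 72.0)")
amp = phase_to_displacement(np.ptp(bundle.fused_phase), config)
print(f"peak-to-peak chest excursion: {amp * 1e3:.2f} mm")
```

prints

```
range resolution: 0.0451 m
respiration: 0.250 Hz (truth 0.250)
heart rate:  72.0 bpm (truth 72.0)
peak-to-peak chest excursion: 6.40 mm
```

The simulated chest (3 mm respiration at 0.25 Hz, 0.1 mm heartbeat at
1.2 Hz, 0.7 m from the radar) is recovered exactly at the spectral
resolution of a 60 s record; the ~6.4 mm excursion is the peak-to-peak
respiratory displacement (2 × 3 mm) plus the heartbeat and noise ripple
riding on it.

A command-line interface mirrors the pipeline stages
(`emowave simulate | extract | process-physio | validate | features |
ratings | classify`); run `emowave --help` for details.

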