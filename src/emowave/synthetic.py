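"""Synthetic generators for every raw modality the pipeline consumes.

These generators exist so the whole chain — raw radar ADC cubes, PPG, GSR
and SAM rating tables — can be exercised and validated without the real
recordings. They emulate the statistical structure the downstream
analysis relies on, not the full physics of the hardware:

* radar: point reflectors (chest + static clutter) with a sinusoidal
  chest-wall displacement model, 12 identical virtual channels with
  independent complex Gaussian receiver noise;
* PPG: a quasi-periodic two-lobe pulse template (systolic peak +
  dicrotic bump) with beat-to-beat interval jitter;
* GSR: a tonic conductance level plus bi-exponential phasic responses,
  reported as resistance within the sensor's 100-2500 kOhm range;
* SAM: integer 1-9 ratings drawn from rounded, clipped normals with
  per-clip population means/SDs.

All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .physio import (GSR_RESISTANCE_RANGE, PhysioSignal,
                     conductance_to_resistance, resistance_to_conductance)
from .radar import AdcCube, RadarConfig

#: Default relative complex-noise SD for "moderate" receiver noise
#: (per real/imaginary sample, relative to the unit-amplitude chest return).
DEFAULT_NOISE_SD = 0.1


@dataclass(frozen=True)
class ChestMotionModel:
    """Chest-wall range trajectory R(t) seen by the radar.

    R(t) = baseline + respiration (+ harmonics) + heartbeat + artifacts.
    Respiration is mm-scale (1-5 mm typical), the heartbeat sub-mm
    (0.05-0.3 mm); ``resp_harmonics`` lists (multiple, relative amplitude)
    pairs riding on the respiration fundamental, and ``motion_artifacts``
    lists (start s, duration s, displacement m) ramp-and-hold events.
    """

    baseline_range: float = 0.7  # m
    resp_rate: float = 0.25  # Hz
    resp_amplitude: float = 3e-3  # m
    heart_rate: float = 1.2  # Hz
    heart_amplitude: float = 1e-4  # m
    resp_harmonics: tuple[tuple[float, float], ...] = ()
    motion_artifacts: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if not 0 < self.resp_rate <= 0.5:
            raise ValueError("resp_rate must lie in (0, 0.5] Hz")
        if not 0.5 < self.heart_rate < 3:
            raise ValueError("heart_rate must lie in (0.5, 3) Hz")
        if self.resp_amplitude <= 0 or self.heart_amplitude <= 0:
            raise ValueError("motion amplitudes must be positive")
        if self.baseline_range <= 0:
            raise ValueError("baseline_range must be positive")

    def range_at(self, t: np.ndarray) -> np.ndarray:
        """Evaluate R(t) [m] on a slow-time grid."""
        t = np.asarray(t, dtype=float)
        r = np.full_like(t, self.baseline_range)
        r += self.resp_amplitude * np.sin(2 * np.pi * self.resp_rate * t)
        for multiple, rel in self.resp_harmonics:
            r += (self.resp_amplitude * rel
                  * np.sin(2 * np.pi * multiple * self.resp_rate * t))
        r += self.heart_amplitude * np.sin(2 * np.pi * self.heart_rate * t)
        for start, duration, displacement in self.motion_artifacts:
            if duration > 0:
                ramp = np.clip((t - start) / duration, 0.0, 1.0)
            else:
                ramp = (t >= start).astype(float)
            r += displacement * ramp
        return r


@dataclass(frozen=True)
class SceneModel:
    """A chest target plus static clutter in front of the radar.

    ``target=None`` simulates an empty (clutter-only) scene."""

    target: ChestMotionModel | None = field(default_factory=ChestMotionModel)
    clutter: tuple[tuple[float, float], ...] = ()  # (range m, rel amplitude)
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for rng_m, amp in self.clutter:
            if amp < 0:
                raise ValueError("clutter amplitudes must be >= 0")
            if rng_m <= 0:
                raise ValueError("clutter ranges must be positive")


@dataclass(frozen=True)
class SAMGeneratorSpec:
    """Population means/SDs of the per-clip SAM rating distributions.

    ``clip_stats`` maps clip_id -> ((v_mean, v_sd), (a_mean, a_sd),
    (d_mean, d_sd)) on the 1-9 scale.
    """

    n_participants: int
    clip_stats: dict[int, tuple[tuple[float, float], ...]]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for clip, stats in self.clip_stats.items():
            if len(stats) != 3:
                raise ValueError("each clip needs (valence, arousal, dominance) stats")
            for mean, sd in stats:
                if not 1 <= mean <= 9:
                    raise ValueError(f"clip {clip}: mean {mean} outside [1, 9]")
                if sd < 0:
                    raise ValueError(f"clip {clip}: negative SD")


def _reflector_return(f_if: float, phase_slow: np.ndarray, amplitude: float,
                      t_fast: np.ndarray) -> np.ndarray:
    """One reflector's (fast x slow) complex contribution for all chirps."""
    fast = np.exp(1j * 2 * np.pi * f_if * t_fast)
    slow = amplitude * np.exp(1j * phase_slow)
    return fast[:, None] * slow[None, :]


def simulate_adc_cube(config: RadarConfig, scene: SceneModel,
                      duration: float) -> AdcCube:
    """Simulate a raw ADC cube for ``duration`` seconds.

    Each reflector at range R contributes, per chirp,
    ``A * exp(j*(2*pi*f_IF*t_fast + 4*pi*R(t_slow)/lambda))`` with the beat
    frequency ``f_IF = S*2*R0/c`` evaluated at the reflector's nominal
    range: sub-millimetre chest motion moves the beat tone by ~1e-4 of a
    range bin, so only the slow-time carrier phase carries the motion
    (stop-and-hop, small-displacement approximation). The chirp-internal
    trajectory is likewise frozen at the chirp epoch.

    All virtual channels observe the identical reflector return and differ
    only in their independent complex Gaussian noise.
    """
    if duration < 1.0:
        raise ValueError("duration must be >= 1 s")
    n_chirps = int(round(config.slow_time_rate * duration))
    t_slow = np.arange(n_chirps) / config.slow_time_rate
    t_fast = np.arange(config.adc_samples) / config.adc_sample_rate
    lam = config.wavelength
    nyquist = config.adc_sample_rate / 2.0

    from .radar import C_LIGHT  # single source for the constant

    def check_alias(r0: float, label: str) -> float:
        f_if = config.slope * 2.0 * r0 / C_LIGHT
        if f_if > nyquist:
            raise ValueError(
                f"{label} at {r0:.3g} m beats at {f_if:.4g} Hz, beyond the "
                f"ADC Nyquist frequency {nyquist:.4g} Hz (aliased)")
        return f_if

    target = scene.target
    if target is None and not scene.clutter:
        raise ValueError("scene has neither a target nor clutter")
    signal = np.zeros((config.adc_samples, n_chirps), dtype=np.complex128)
    if target is not None:
        f_if = check_alias(target.baseline_range, "target")
        signal += _reflector_return(
            f_if, 4 * np.pi * target.range_at(t_slow) / lam, 1.0, t_fast)
    for rng_m, amp in scene.clutter:
        f_if_c = check_alias(rng_m, "clutter reflector")
        phase = np.full(n_chirps, 4 * np.pi * rng_m / lam)
        signal += _reflector_return(f_if_c, phase, amp, t_fast)

    n_ch = config.n_virtual_channels
    cube = np.broadcast_to(signal, (n_ch,) + signal.shape).copy()
    if scene.noise_sd > 0:
        rng = np.random.default_rng(scene.seed)
        scale = scene.noise_sd / np.sqrt(2.0)
        shape = (n_ch,) + signal.shape
        cube += scale * rng.standard_normal(shape, dtype=np.float32)
        cube += 1j * scale * rng.standard_normal(shape, dtype=np.float32)
    return AdcCube(cube)


def _ppg_beat_template(tau: np.ndarray, period: float) -> np.ndarray:
    """Fixed two-lobe pulse shape over one beat: a systolic Gaussian peak
    at 0.3*T and a smaller dicrotic bump at 0.6*T."""
    systolic = np.exp(-0.5 * ((tau - 0.30 * period) / (0.08 * period)) ** 2)
    dicrotic = 0.35 * np.exp(-0.5 * ((tau - 0.60 * period) / (0.12 * period)) ** 2)
    return systolic + dicrotic


def simulate_ppg(heart_rate: float, rate_jitter: float = 0.0, fs: float = 200.0,
                 duration: float = 60.0, noise_sd: float = 0.0,
                 seed: int = 0) -> PhysioSignal:
    """Quasi-periodic PPG pulse train.

    Beat intervals are 1/heart_rate perturbed multiplicatively by
    ``rate_jitter`` (fractional SD); additive white Gaussian noise of SD
    ``noise_sd``. The true systolic-peak times are stored in
    ``meta["beat_times"]`` for use as detector ground truth.
    """
    if fs < 50:
        raise ValueError("fs must be >= 50 Hz")
    if not 0.5 < heart_rate < 3.5:
        raise ValueError("heart_rate must lie in (0.5, 3.5) Hz")
    rng = np.random.default_rng(seed)
    mean_period = 1.0 / heart_rate

    onsets = []
    t = 0.05 * mean_period
    while t < duration:
        onsets.append(t)
        interval = mean_period * (1.0 + rate_jitter * rng.standard_normal())
        t += max(interval, 0.3 * mean_period)
    times = np.arange(int(round(duration * fs))) / fs
    signal = np.zeros_like(times)
    peak_times = []
    for i, onset in enumerate(onsets):
        period = (onsets[i + 1] - onset) if i + 1 < len(onsets) else mean_period
        lo = np.searchsorted(times, onset)
        hi = np.searchsorted(times, onset + period)
        tau = times[lo:hi] - onset
        signal[lo:hi] += _ppg_beat_template(tau, period)
        peak_times.append(onset + 0.30 * period)
    if noise_sd > 0:
        signal = signal + noise_sd * rng.standard_normal(signal.size)
    return PhysioSignal(signal, fs, "a.u.",
                        {"beat_times": np.asarray(peak_times)})


def scr_kernel(t: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Unit-peak bi-exponential skin-conductance-response kernel."""
    if not 0 < rise < decay:
        raise ValueError("need 0 < rise < decay")
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0, np.exp(-t / decay) - np.exp(-t / rise), 0.0)
    t_peak = rise * decay / (decay - rise) * np.log(decay / rise)
    peak = np.exp(-t_peak / decay) - np.exp(-t_peak / rise)
    return out / peak


def simulate_gsr(tonic_kohm: float = 500.0,
                 scr_events: Sequence[tuple[float, float, float, float]] = (),
                 fs: float = 200.0, duration: float = 60.0,
                 noise_sd: float = 0.0, seed: int = 0) -> PhysioSignal:
    """GSR resistance trace [kOhm].

    The conductance is a tonic level (1000/tonic_kohm uS) plus unit-peak
    bi-exponential responses, one per (onset s, amplitude uS, rise s,
    decay s) event, plus white noise in uS; the trace is then inverted to
    resistance and clipped to the sensor's 100-2500 kOhm range.
    """
    lo, hi = GSR_RESISTANCE_RANGE
    if not lo <= tonic_kohm <= hi:
        raise ValueError(f"tonic_kohm must lie in [{lo}, {hi}]")
    rng = np.random.default_rng(seed)
    times = np.arange(int(round(duration * fs))) / fs
    conductance = np.full_like(times, resistance_to_conductance(tonic_kohm))
    for onset, amplitude, rise, decay in scr_events:
        conductance += amplitude * scr_kernel(times - onset, rise, decay)
    if noise_sd > 0:
        conductance = conductance + noise_sd * rng.standard_normal(times.size)
    conductance = np.clip(conductance,
                          resistance_to_conductance(hi),
                          resistance_to_conductance(lo))
    resistance = conductance_to_resistance(conductance)
    return PhysioSignal(resistance, fs, "kohm")


def simulate_sam_ratings(spec: SAMGeneratorSpec) -> pd.DataFrame:
    """Integer SAM ratings for every participant x clip x scale.

    Ratings are normal draws with the clip's population mean/SD, rounded
    to the nearest integer and clipped to [1, 9]. Returns a long-format
    frame with columns participant_id ("01"...), clip_id, valence,
    arousal, dominance.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    scales = ("valence", "arousal", "dominance")
    for p in range(1, spec.n_participants + 1):
        for clip_id in sorted(spec.clip_stats):
            row: dict[str, object] = {"participant_id": f"{p:02d}",
                                      "clip_id": clip_id}
            for scale, (mean, sd) in zip(scales, spec.clip_stats[clip_id]):
                draw = rng.normal(mean, sd) if sd > 0 else mean
                row[scale] = int(np.clip(np.rint(draw), 1, 9))
            rows.append(row)
    return pd.DataFrame(rows)
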