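"""Conditioning of the contact physiological channels (PPG, GSR).

PPG is band-passed to the pulsatile band, linearly detrended and smoothed
with a short moving average; GSR (recorded as skin *resistance* in kOhm)
is inverted to conductance in microsiemens and low-passed. Both chains
are zero-phase so beat timing and response latencies are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.signal import butter, detrend, sosfiltfilt

PPG_BAND = (0.6, 5.0)  # Hz
PPG_FILTER_ORDER = 4
PPG_SMOOTH_SECONDS = 0.1  # moving-average window (20 samples at 200 Hz)
GSR_CUTOFF = 1.0  # Hz low-pass on conductance
GSR_FILTER_ORDER = 3
GSR_RESISTANCE_RANGE = (100.0, 2500.0)  # kOhm, sensor measurement range


@dataclass
class PhysioSignal:
    """A uniformly sampled 1-D physiological series.

    ``unit`` is "a.u." for PPG, "kohm" for raw GSR resistance and "uS" for
    GSR conductance; ``meta`` carries generator ground truth (e.g. true
    beat times) when the signal is synthetic.
    """

    samples: np.ndarray
    fs: float
    unit: str
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge truncation (shorter window at the
    boundaries), so the output has the same length and no phase lag."""
    if window < 1:
        raise ValueError("window must be >= 1")
    kernel = np.ones(window)
    sums = np.convolve(x, kernel, mode="same")
    counts = np.convolve(np.ones_like(x), kernel, mode="same")
    return sums / counts


def process_ppg(raw: PhysioSignal) -> PhysioSignal:
    """PPG chain: 0.6-5 Hz 4th-order Butterworth band-pass (zero-phase),
    least-squares linear detrend, then a centered 0.1 s moving average.
    """
    if raw.unit != "a.u.":
        raise ValueError(f"expected PPG in a.u., got unit {raw.unit!r}")
    sos = butter(PPG_FILTER_ORDER, PPG_BAND, btype="bandpass",
                 fs=raw.fs, output="sos")
    min_len = 3 * (2 * sos.shape[0] * 3 + 1)
    if raw.samples.size < min_len:
        raise ValueError(f"record too short for stable filtering (<{min_len} samples)")
    filtered = sosfiltfilt(sos, raw.samples)
    detrended = detrend(filtered, type="linear")
    window = max(1, int(round(PPG_SMOOTH_SECONDS * raw.fs)))
    smoothed = moving_average(detrended, window)
    return PhysioSignal(smoothed, raw.fs, "a.u.", dict(raw.meta))


def resistance_to_conductance(resistance_kohm: np.ndarray) -> np.ndarray:
    """kOhm -> microsiemens: G [uS] = 1000 / R [kOhm] (100 kOhm -> 10 uS)."""
    r = np.asarray(resistance_kohm, dtype=float)
    if np.any(r <= 0):
        raise ValueError("resistance must be strictly positive")
    return 1000.0 / r


def conductance_to_resistance(conductance_us: np.ndarray) -> np.ndarray:
    """Inverse of :func:`resistance_to_conductance` (exact involution)."""
    g = np.asarray(conductance_us, dtype=float)
    if np.any(g <= 0):
        raise ValueError("conductance must be strictly positive")
    return 1000.0 / g


def process_gsr(raw: PhysioSignal) -> PhysioSignal:
    """GSR chain: invert resistance to conductance, then a 3rd-order 1 Hz
    Butterworth low-pass (zero-phase). Output unit is microsiemens."""
    if raw.unit != "kohm":
        raise ValueError(f"expected GSR resistance in kohm, got unit {raw.unit!r}")
    conductance = resistance_to_conductance(raw.samples)
    sos = butter(GSR_FILTER_ORDER, GSR_CUTOFF, btype="lowpass",
                 fs=raw.fs, output="sos")
    smoothed = sosfiltfilt(sos, conductance)
    return PhysioSignal(smoothed, raw.fs, "uS", dict(raw.meta))
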