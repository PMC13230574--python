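"""Signal-quality validation: band-split SNR and heart-rate agreement.

SNR splits a record at a cutoff frequency into a low-pass "signal" part
and a high-pass "noise" part and reports 10*log10 of their mean-square
ratio (15 Hz boundary for PPG, 1 Hz for GSR). Heart-rate agreement
compares the dominant spectral frequency of the radar heartbeat waveform
against the PPG reference, trial by trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .physio import PhysioSignal

PPG_SNR_CUTOFF = 15.0  # Hz
GSR_SNR_CUTOFF = 1.0  # Hz
SNR_FILTER_ORDER = 3

#: Default dominant-frequency search bands [Hz]
HEART_RATE_BAND = (0.8, 2.0)
RESPIRATION_RATE_BAND = (0.1, 0.5)

#: Spectral grid spacing ceiling for dominant-frequency search [Hz]
FREQUENCY_GRID = 0.005


@dataclass
class HRAgreement:
    """Per-trial absolute heart-rate errors and their summary statistics."""

    absolute_errors: np.ndarray  # bpm
    mae: float  # bpm
    median_ae: float  # bpm
    sd_ae: float  # bpm
    mean_relative_error: float  # fraction


def snr_db(signal: PhysioSignal, cutoff: float,
           order: int = SNR_FILTER_ORDER) -> float:
    """Band-split SNR [dB] at ``cutoff`` Hz.

    Zero-phase Butterworth low-pass -> mean square M_signal; matching
    high-pass -> mean square M_noise; returns 10*log10(M_signal/M_noise).
    Exactly zero noise power yields +inf (distinct sentinel).
    """
    if not 0 < cutoff < signal.fs / 2:
        raise ValueError("cutoff must lie in (0, fs/2)")
    x = signal.samples
    low = sosfiltfilt(butter(order, cutoff, btype="lowpass",
                             fs=signal.fs, output="sos"), x)
    high = sosfiltfilt(butter(order, cutoff, btype="highpass",
                              fs=signal.fs, output="sos"), x)
    m_signal = float(np.mean(low ** 2))
    m_noise = float(np.mean(high ** 2))
    if m_noise == 0.0:
        return float("inf")
    return 10.0 * np.log10(m_signal / m_noise)


def dominant_frequency(signal: np.ndarray, fs: float,
                       band: tuple[float, float]) -> float:
    """Frequency [Hz] of the magnitude-spectrum maximum within ``band``.

    The spectrum is zero-padded so the frequency grid is no coarser than
    0.005 Hz regardless of record length.
    """
    x = np.asarray(signal, dtype=float)
    lo, hi = band
    if not 0 < lo < hi <= fs / 2:
        raise ValueError(f"band {band} not within (0, fs/2)")
    nfft = int(2 ** np.ceil(np.log2(max(x.size, fs / FREQUENCY_GRID))))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    spectrum = np.abs(np.fft.rfft(x, n=nfft))
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ValueError(f"band {band} contains no spectral bins")
    return float(freqs[mask][np.argmax(spectrum[mask])])


def hr_agreement(mm_hr: np.ndarray, ref_hr: np.ndarray) -> HRAgreement:
    """Summary of |radar HR - reference HR| over trials [bpm]."""
    mm = np.asarray(mm_hr, dtype=float)
    ref = np.asarray(ref_hr, dtype=float)
    if mm.shape != ref.shape or mm.size < 1:
        raise ValueError("mm_hr and ref_hr must be equal-length, non-empty")
    if np.any(ref <= 0):
        raise ValueError("reference heart rates must be positive")
    errors = np.abs(mm - ref)
    return HRAgreement(
        absolute_errors=errors,
        mae=float(errors.mean()),
        median_ae=float(np.median(errors)),
        sd_ae=float(errors.std(ddof=1)) if errors.size > 1 else 0.0,
        mean_relative_error=float(np.mean(errors / ref)),
    )
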