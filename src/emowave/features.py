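"""Windowed feature extraction for the three modalities.

Features are computed per 5-second window over the final 60 seconds of a
trial (12 windows, no overlap): 32 features for the radar vital sign, 28
for PPG and 24 for GSR conductance. The schemas are fixed, ordered and
length-checked on every call.

Heart-rate-variability features need beat-to-beat intervals; beats are
located with prominence-based peak picking with a 0.45 s refractory
period (the detector is isolated behind :func:`detect_beats` so a
template-matching segmenter can be substituted). Windows too short to
contain enough beats fall back to the trial-level HRV computed over the
whole 60-s tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, hilbert, periodogram

from .emd import empirical_mode_decomposition

# ---------------------------------------------------------------------------
# windowing

@dataclass(frozen=True)
class WindowSpec:
    """Analysis-tail windowing: the final ``tail_seconds`` of a trial cut
    into non-overlapping ``window_seconds`` slices."""

    tail_seconds: float = 60.0
    window_seconds: float = 5.0
    step_seconds: float = 5.0

    def __post_init__(self) -> None:
        if min(self.tail_seconds, self.window_seconds, self.step_seconds) <= 0:
            raise ValueError("window timings must be positive")

    @property
    def n_windows(self) -> int:
        n = self.tail_seconds / self.step_seconds
        if abs(n - round(n)) > 1e-9:
            raise ValueError("tail must hold an integral number of windows")
        return int(round(n))


def window_slices(n_samples: int, fs: float,
                  spec: WindowSpec = WindowSpec()) -> list[tuple[int, int]]:
    """Half-open [start, end) index pairs covering exactly the final tail."""
    tail = int(round(spec.tail_seconds * fs))
    if n_samples < tail:
        raise ValueError(
            f"record of {n_samples} samples shorter than the "
            f"{spec.tail_seconds} s analysis tail at fs={fs}")
    start0 = n_samples - tail
    step = int(round(spec.step_seconds * fs))
    width = int(round(spec.window_seconds * fs))
    return [(start0 + i * step, start0 + i * step + width)
            for i in range(spec.n_windows)]


# ---------------------------------------------------------------------------
# beat detection and HRV

@dataclass
class BeatSeries:
    """Detected beat times [s] and the NN (beat-to-beat) intervals [s]."""

    beat_times: np.ndarray
    nn_intervals: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.beat_times, dtype=float)
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("beat_times must be strictly increasing")
        self.beat_times = t
        self.nn_intervals = np.diff(t)


MIN_BEAT_SEPARATION = 0.45  # s, refractory period (~133 bpm ceiling)


def detect_beats(heartbeat: np.ndarray, fs: float,
                 min_separation: float = MIN_BEAT_SEPARATION) -> BeatSeries:
    """Locate beats as local maxima with an adaptive prominence threshold.

    Prominence must exceed half the signal's robust amplitude (5th-95th
    percentile span); peaks closer than ``min_separation`` are merged.
    A flat or empty signal yields an empty series.
    """
    x = np.asarray(heartbeat, dtype=float)
    span = np.percentile(x, 95) - np.percentile(x, 5) if x.size else 0.0
    if span <= 0:
        return BeatSeries(np.empty(0))
    peaks, _ = find_peaks(x, distance=max(1, int(round(min_separation * fs))),
                          prominence=0.5 * span)
    return BeatSeries(peaks / fs)


HRV_FEATURES = ("meanNN", "medianNN", "SDNN", "RMSSD", "pNN50",
                "meanRate", "sdRate", "HRVTi", "SD1")

HRVTI_BIN_WIDTH = 1.0 / 128.0  # s, conventional 7.8125 ms histogram bin


def hrv_features(beats: BeatSeries) -> dict[str, float]:
    """Nine time-domain / geometric / Poincare HRV statistics.

    meanNN/medianNN/SDNN/RMSSD/SD1 in seconds, pNN50 in percent,
    meanRate/sdRate in bpm (statistics of 60/NN), HRVTi dimensionless
    (interval count over the modal histogram bin count). SD1 is the RMS
    distance of Poincare points perpendicular to the identity line, which
    equals RMSSD/sqrt(2) identically. Fewer than 3 NN intervals yields
    NaNs (flagged missing).
    """
    nn = beats.nn_intervals
    if nn.size < 3:
        return {name: float("nan") for name in HRV_FEATURES}
    diffs = np.diff(nn)
    rmssd = float(np.sqrt(np.mean(diffs ** 2)))
    rates = 60.0 / nn
    edges = np.arange(nn.min(), nn.max() + 2 * HRVTI_BIN_WIDTH, HRVTI_BIN_WIDTH)
    counts, _ = np.histogram(nn, bins=edges)
    sd1 = float(np.sqrt(np.mean((diffs / np.sqrt(2.0)) ** 2)))
    return {
        "meanNN": float(np.mean(nn)),
        "medianNN": float(np.median(nn)),
        "SDNN": float(np.std(nn, ddof=1)),
        "RMSSD": rmssd,
        "pNN50": float(100.0 * np.mean(np.abs(diffs) > 0.050)),
        "meanRate": float(np.mean(rates)),
        "sdRate": float(np.std(rates, ddof=1)),
        "HRVTi": float(nn.size / counts.max()),
        "SD1": sd1,
    }


# ---------------------------------------------------------------------------
# scalar descriptors

def nsi(signal: np.ndarray, n_segments: int = 10) -> float:
    """Non-stationarity index: SD of the per-segment means of the
    variance-normalized signal. Zero-variance input returns 0."""
    x = np.asarray(signal, dtype=float)
    if x.size < n_segments:
        raise ValueError("signal shorter than n_segments")
    sd = x.std()
    if sd == 0:
        return 0.0
    z = (x - x.mean()) / sd
    means = np.array([seg.mean() for seg in np.array_split(z, n_segments)])
    return float(means.std())


def hfd(signal: np.ndarray, kmax: int = 10) -> float:
    """Higuchi fractal dimension via the curve-length regression.

    For each lag k the mean normalized curve length L(k) is computed over
    the k decimation offsets; the HFD is the slope of log L(k) against
    log(1/k). Near 1 for smooth curves, near 2 for white noise.
    """
    x = np.asarray(signal, dtype=float)
    n = x.size
    if n < 10 * kmax:
        raise ValueError(f"need at least {10 * kmax} samples for kmax={kmax}")
    lengths = []
    for k in range(1, kmax + 1):
        lk = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if idx.size < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / ((idx.size - 1) * k)
            lk.append(dist * norm / k)
        lengths.append(np.mean(lk))
    lengths = np.asarray(lengths)
    if np.any(lengths <= 0):  # constant signal: define dimension of a point/line
        return 1.0
    k = np.arange(1, kmax + 1)
    slope = np.polyfit(np.log(1.0 / k), np.log(lengths), 1)[0]
    return float(slope)


def psd_band_energy(signal: np.ndarray, fs: float,
                    band: tuple[float, float]) -> float:
    """Mean periodogram PSD over [lo, hi) Hz.

    The periodogram (rectangular window) is zero-padded to a grid of at
    most 0.025 Hz so that bands narrower than the raw resolution of a
    short window are still populated.
    """
    x = np.asarray(signal, dtype=float)
    lo, hi = band
    if not 0 <= lo < hi <= fs / 2:
        raise ValueError(f"band {band} not within (0, fs/2)")
    nfft = max(x.size, int(np.ceil(fs / 0.025)))
    freqs, psd = periodogram(x, fs=fs, window="boxcar", nfft=nfft)
    mask = (freqs >= lo) & (freqs < hi)
    if not mask.any():
        raise ValueError(f"band {band} empty after discretization")
    return float(psd[mask].mean())


def _psd_in_band(signal: np.ndarray, fs: float,
                 band: tuple[float, float]) -> np.ndarray:
    x = np.asarray(signal, dtype=float)
    nfft = max(x.size, int(np.ceil(fs / 0.025)))
    freqs, psd = periodogram(x, fs=fs, window="boxcar", nfft=nfft)
    return psd[(freqs >= band[0]) & (freqs <= band[1])]


def hht_features(signal: np.ndarray, fs: float, n_imfs: int = 4,
                 edge_trim: float = 0.05) -> dict[str, float]:
    """Mean instantaneous frequency and amplitude of the first ``n_imfs``
    intrinsic mode functions (Hilbert-Huang).

    Instantaneous frequency is the derivative of the unwrapped analytic
    phase; the outer ``edge_trim`` fraction of samples on each side is
    discarded to avoid Hilbert edge artifacts. IMFs the decomposition does
    not yield are reported as 0 (missing-flag convention).
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 100:
        raise ValueError("need at least 100 samples")
    out: dict[str, float] = {}
    imfs = ([] if np.ptp(x) == 0
            else empirical_mode_decomposition(x, max_imfs=n_imfs))
    trim = max(1, int(round(edge_trim * x.size)))
    for i in range(n_imfs):
        f_key, a_key = f"imf{i + 1}_freq", f"imf{i + 1}_amp"
        if i >= len(imfs):
            out[f_key] = 0.0
            out[a_key] = 0.0
            continue
        analytic = hilbert(imfs[i])
        inst_freq = np.diff(np.unwrap(np.angle(analytic))) * fs / (2 * np.pi)
        out[f_key] = float(np.mean(inst_freq[trim:-trim]))
        out[a_key] = float(np.mean(np.abs(analytic)[trim:-trim]))
    return out


# ---------------------------------------------------------------------------
# per-modality feature vectors

RESPIRATION_PSD_BANDS = ((0.0, 0.1), (0.1, 0.2), (0.2, 0.3), (0.3, 0.4))
HEARTBEAT_PSD_BANDS = ((1.0, 1.3), (1.3, 1.6), (1.6, 1.8))
GSR_PSD_BAND = (0.0, 2.0)

_HHT_NAMES = tuple(f"imf{i}_{kind}" for i in range(1, 5)
                   for kind in ("freq", "amp"))

MMWAVE_FEATURES: tuple[str, ...] = (
    ("vs_mean", "vs_sd",
     "vs_mad1", "vs_mad2", "vs_norm_mad1", "vs_norm_mad2",
     "vs_nsi", "vs_hfd")
    + tuple(f"resp_psd_{lo:g}_{hi:g}" for lo, hi in RESPIRATION_PSD_BANDS)
    + tuple(f"heart_psd_{lo:g}_{hi:g}" for lo, hi in HEARTBEAT_PSD_BANDS)
    + _HHT_NAMES + HRV_FEATURES
)

PPG_FEATURES: tuple[str, ...] = (
    ("sig_mean", "sig_sd",
     "sig_mad1", "sig_mad2", "sig_norm_mad1", "sig_norm_mad2",
     "sig_nsi", "sig_hfd")
    + tuple(f"sig_psd_{lo:g}_{hi:g}" for lo, hi in HEARTBEAT_PSD_BANDS)
    + _HHT_NAMES + HRV_FEATURES
)

_GSR_STAT_NAMES = ("median", "mean", "sd", "min", "max", "nrange")
GSR_FEATURES: tuple[str, ...] = (
    tuple(f"sig_{s}" for s in _GSR_STAT_NAMES)
    + tuple(f"d1_{s}" for s in _GSR_STAT_NAMES)
    + tuple(f"d2_{s}" for s in _GSR_STAT_NAMES)
    + ("psd_median", "psd_mean", "psd_sd", "psd_max", "psd_min", "psd_range")
)

assert len(MMWAVE_FEATURES) == 32
assert len(PPG_FEATURES) == 28
assert len(GSR_FEATURES) == 24


@dataclass
class FeatureMatrix:
    """windows x features table with a fixed, ordered schema."""

    values: np.ndarray
    schema: tuple[str, ...]
    signal_kind: str  # "mmwave" | "ppg" | "gsr"

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        expected = {"mmwave": MMWAVE_FEATURES, "ppg": PPG_FEATURES,
                    "gsr": GSR_FEATURES}[self.signal_kind]
        if tuple(self.schema) != expected:
            raise ValueError(f"schema does not match the fixed "
                             f"{self.signal_kind} feature schema")
        if self.values.shape[1] != len(expected):
            raise ValueError(
                f"expected {len(expected)} columns, got {self.values.shape[1]}")


def _mad_block(x: np.ndarray) -> list[float]:
    """mean|d1|, mean|d2| of the signal and of its z-normalized copy."""
    d1 = float(np.mean(np.abs(np.diff(x))))
    d2 = float(np.mean(np.abs(np.diff(x, n=2))))
    sd = x.std()
    if sd == 0:
        return [d1, d2, 0.0, 0.0]
    z = (x - x.mean()) / sd
    return [d1, d2,
            float(np.mean(np.abs(np.diff(z)))),
            float(np.mean(np.abs(np.diff(z, n=2))))]


def mmwave_feature_vector(vital_sign: np.ndarray, respiration: np.ndarray,
                          heartbeat: np.ndarray, fs: float,
                          beats: BeatSeries) -> np.ndarray:
    """The 32 radar features for one window (see MMWAVE_FEATURES)."""
    vs = np.asarray(vital_sign, dtype=float)
    vals = [float(vs.mean()), float(vs.std())]
    vals += _mad_block(vs)
    vals += [nsi(vs), hfd(vs)]
    vals += [psd_band_energy(respiration, fs, b) for b in RESPIRATION_PSD_BANDS]
    vals += [psd_band_energy(heartbeat, fs, b) for b in HEARTBEAT_PSD_BANDS]
    vals += list(hht_features(vs, fs).values())
    vals += list(hrv_features(beats).values())
    out = np.asarray(vals)
    assert out.size == 32
    return out


def ppg_feature_vector(processed_ppg: np.ndarray, fs: float,
                       beats: BeatSeries) -> np.ndarray:
    """The 28 PPG features for one window (see PPG_FEATURES)."""
    x = np.asarray(processed_ppg, dtype=float)
    vals = [float(x.mean()), float(x.std())]
    vals += _mad_block(x)
    vals += [nsi(x), hfd(x)]
    vals += [psd_band_energy(x, fs, b) for b in HEARTBEAT_PSD_BANDS]
    vals += list(hht_features(x, fs).values())
    vals += list(hrv_features(beats).values())
    out = np.asarray(vals)
    assert out.size == 28
    return out


def _stat_block(x: np.ndarray) -> list[float]:
    mean = float(x.mean())
    span = float(x.max() - x.min())
    nrange = span / mean if mean != 0 else 0.0
    return [float(np.median(x)), mean, float(x.std()),
            float(x.min()), float(x.max()), nrange]


def gsr_feature_vector(conductance: np.ndarray, fs: float) -> np.ndarray:
    """The 24 GSR features for one window (see GSR_FEATURES).

    Six order statistics of the signal, its first and second discrete
    derivatives, plus six statistics of the 0-2 Hz periodogram PSD.
    """
    x = np.asarray(conductance, dtype=float)
    vals = _stat_block(x) + _stat_block(np.diff(x)) + _stat_block(np.diff(x, n=2))
    psd = _psd_in_band(x, fs, GSR_PSD_BAND)
    vals += [float(np.median(psd)), float(psd.mean()), float(psd.std()),
             float(psd.max()), float(psd.min()), float(psd.max() - psd.min())]
    out = np.asarray(vals)
    assert out.size == 24
    return out


# ---------------------------------------------------------------------------
# trial-level drivers

def _window_beats(beats: BeatSeries, t0: float, t1: float,
                  fallback: dict[str, float]) -> dict[str, float]:
    mask = (beats.beat_times >= t0) & (beats.beat_times < t1)
    local = hrv_features(BeatSeries(beats.beat_times[mask]))
    if np.isnan(local["meanNN"]):
        return fallback
    return local


def _with_hrv(vector: np.ndarray, schema: tuple[str, ...],
              hrv: dict[str, float]) -> np.ndarray:
    out = vector.copy()
    for i, name in enumerate(schema):
        if name in hrv:
            out[i] = hrv[name]
    return out


def extract_mmwave_features(vital_sign: np.ndarray, respiration: np.ndarray,
                            heartbeat: np.ndarray, fs: float,
                            spec: WindowSpec = WindowSpec()) -> FeatureMatrix:
    """Per-window radar feature matrix over the final analysis tail.

    Beats are detected once on the tail of the heartbeat waveform; windows
    with too few local beats carry the trial-level HRV forward.
    """
    slices = window_slices(vital_sign.size, fs, spec)
    tail0 = slices[0][0]
    beats = detect_beats(heartbeat[tail0:], fs)
    trial_hrv = hrv_features(beats)
    rows = []
    for start, end in slices:
        vec = mmwave_feature_vector(vital_sign[start:end],
                                    respiration[start:end],
                                    heartbeat[start:end], fs,
                                    BeatSeries(np.empty(0)))
        hrv = _window_beats(beats, (start - tail0) / fs, (end - tail0) / fs,
                            trial_hrv)
        rows.append(_with_hrv(vec, MMWAVE_FEATURES, hrv))
    return FeatureMatrix(np.vstack(rows), MMWAVE_FEATURES, "mmwave")


def extract_ppg_features(processed_ppg: np.ndarray, fs: float,
                         spec: WindowSpec = WindowSpec()) -> FeatureMatrix:
    """Per-window PPG feature matrix over the final analysis tail."""
    slices = window_slices(processed_ppg.size, fs, spec)
    tail0 = slices[0][0]
    beats = detect_beats(processed_ppg[tail0:], fs)
    trial_hrv = hrv_features(beats)
    rows = []
    for start, end in slices:
        vec = ppg_feature_vector(processed_ppg[start:end], fs,
                                 BeatSeries(np.empty(0)))
        hrv = _window_beats(beats, (start - tail0) / fs, (end - tail0) / fs,
                            trial_hrv)
        rows.append(_with_hrv(vec, PPG_FEATURES, hrv))
    return FeatureMatrix(np.vstack(rows), PPG_FEATURES, "ppg")


def extract_gsr_features(conductance: np.ndarray, fs: float,
                         spec: WindowSpec = WindowSpec()) -> FeatureMatrix:
    """Per-window GSR feature matrix over the final analysis tail."""
    rows = [gsr_feature_vector(conductance[s:e], fs)
            for s, e in window_slices(conductance.size, fs, spec)]
    return FeatureMatrix(np.vstack(rows), GSR_FEATURES, "gsr")
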