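"""Empirical mode decomposition by cubic-spline envelope sifting.

Classic Huang-style EMD: each intrinsic mode function (IMF) is obtained
by repeatedly subtracting the mean of the upper and lower cubic-spline
envelopes of the local extrema until the standard Cauchy-type stopping
criterion is met; the IMF is removed from the residual and the process
repeats. Envelope end conditions use mirrored edge extrema, which keeps
the splines from diverging at the boundaries.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import argrelextrema


def _extrema_with_mirrored_edges(x: np.ndarray, idx: np.ndarray,
                                 n: int) -> tuple[np.ndarray, np.ndarray]:
    """Extend extrema (positions, values) by mirroring the two outermost
    extrema across each end of the record."""
    pos = idx.astype(float)
    val = x[idx]
    left_pos = -pos[:2][::-1]
    left_val = val[:2][::-1]
    right_pos = 2 * (n - 1) - pos[-2:][::-1]
    right_val = val[-2:][::-1]
    return (np.concatenate([left_pos, pos, right_pos]),
            np.concatenate([left_val, val, right_val]))


def _mean_envelope(x: np.ndarray) -> np.ndarray | None:
    """Mean of the upper/lower spline envelopes, or None if the signal has
    too few extrema to be sifted further."""
    n = x.size
    maxima = argrelextrema(x, np.greater)[0]
    minima = argrelextrema(x, np.less)[0]
    if maxima.size < 2 or minima.size < 2:
        return None
    up_pos, up_val = _extrema_with_mirrored_edges(x, maxima, n)
    lo_pos, lo_val = _extrema_with_mirrored_edges(x, minima, n)
    t = np.arange(n)
    upper = CubicSpline(up_pos, up_val)(t)
    lower = CubicSpline(lo_pos, lo_val)(t)
    return (upper + lower) / 2.0


def empirical_mode_decomposition(signal: np.ndarray, max_imfs: int = 4,
                                 max_siftings: int = 64,
                                 sd_threshold: float = 0.2) -> list[np.ndarray]:
    """Decompose ``signal`` into up to ``max_imfs`` IMFs (fast to slow).

    Sifting of each candidate stops when the relative change
    sum((h_prev - h)^2) / sum(h_prev^2) drops below ``sd_threshold`` or
    after ``max_siftings`` iterations. Returns fewer IMFs when the
    residual becomes monotonic.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < 10:
        raise ValueError("signal must be 1-D with at least 10 samples")
    residual = x.copy()
    imfs: list[np.ndarray] = []
    for _ in range(max_imfs):
        h = residual.copy()
        if _mean_envelope(h) is None:
            break
        for _ in range(max_siftings):
            mean_env = _mean_envelope(h)
            if mean_env is None:
                break
            h_new = h - mean_env
            denom = np.sum(h ** 2)
            sd = np.sum((h - h_new) ** 2) / denom if denom > 0 else 0.0
            h = h_new
            if sd < sd_threshold:
                break
        imfs.append(h)
        residual = residual - h
    return imfs
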