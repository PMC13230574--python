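"""Self-assessment (SAM) rating statistics and label construction.

Covers the rating-consistency analysis (per-clip coefficient of
variation, tie-aware Spearman rank correlation), the valence-arousal
quadrant view of the stimulus set, and the threshold-5 binarization that
turns 1-9 ratings into low/high classification labels (threshold hits
are excluded).

``CLIP_RATING_STATS`` holds the published per-clip rating means/SDs of
the 18 film-clip stimuli, and ``SAMPLE_DISTRIBUTION`` the published
window-level class counts, both from the public multimodal emotion
dataset (Zenodo record 10.5281/zenodo.15825931); they serve as reference
inputs for reproducing the dataset's summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from scipy.stats import t as t_dist

SCALES = ("valence", "arousal", "dominance")

# Per-clip (mean, SD) of the SAM ratings for the 18 stimulus clips:
# columns are valence, arousal, dominance.
_CLIP_STATS_RAW = [
    (1, 6.87, 0.92, 5.60, 1.68, 6.67, 1.23),
    (2, 6.47, 0.99, 4.87, 1.88, 7.00, 0.76),
    (3, 4.73, 1.49, 6.53, 1.30, 6.13, 1.51),
    (4, 5.33, 1.18, 5.80, 2.01, 6.47, 1.19),
    (5, 6.93, 0.70, 6.60, 1.30, 5.40, 1.92),
    (6, 7.00, 1.00, 4.87, 1.46, 5.93, 1.53),
    (7, 6.20, 1.15, 2.73, 1.75, 6.93, 1.39),
    (8, 5.60, 0.74, 3.73, 1.39, 6.67, 1.40),
    (9, 3.27, 1.39, 5.87, 1.36, 4.53, 1.68),
    (10, 4.20, 1.08, 3.80, 1.74, 6.20, 1.47),
    (11, 5.47, 2.26, 5.53, 1.55, 5.40, 1.92),
    (12, 2.67, 1.40, 7.60, 0.99, 3.40, 1.18),
    (13, 3.60, 0.99, 6.13, 1.73, 4.27, 1.53),
    (14, 3.40, 0.91, 7.20, 1.32, 3.93, 1.91),
    (15, 2.87, 0.92, 5.07, 1.58, 4.67, 1.63),
    (16, 2.93, 1.03, 4.87, 1.51, 4.80, 2.11),
    (17, 4.27, 1.10, 3.87, 2.03, 6.07, 1.71),
    (18, 4.47, 1.13, 6.07, 2.22, 5.40, 1.64),
]

CLIP_RATING_STATS = pd.DataFrame(
    _CLIP_STATS_RAW,
    columns=["clip_id", "valence_mean", "valence_sd", "arousal_mean",
             "arousal_sd", "dominance_mean", "dominance_sd"],
).set_index("clip_id")

#: Published window-level sample counts after threshold-5 binarization:
#: scale -> (low, high).
SAMPLE_DISTRIBUTION = {
    "valence": (1344, 1128),
    "arousal": (960, 1800),
    "dominance": (1068, 1860),
}

N_CLIPS = 18
RATING_MIN, RATING_MAX = 1, 9
LABEL_THRESHOLD = 5


@dataclass
class CVSummary:
    """Per-clip coefficients of variation plus their mean/SD, per scale."""

    per_clip_cv: dict[str, np.ndarray]
    mean_cv: dict[str, float]
    sd_cv: dict[str, float]


def coefficient_of_variation(values: np.ndarray) -> float:
    """CV = sample SD / mean. Requires >= 2 values and a non-zero mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    mean = x.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(x.std(ddof=1) / mean)


def cv_from_summary(means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    """Per-clip CVs directly from published (mean, SD) pairs."""
    means = np.asarray(means, dtype=float)
    if np.any(means == 0):
        raise ValueError("CV undefined for zero mean")
    return np.asarray(sds, dtype=float) / means


def cv_summary_from_table(stats: pd.DataFrame = CLIP_RATING_STATS) -> CVSummary:
    """CV summary per scale from a per-clip mean/SD table."""
    per_clip, mean_cv, sd_cv = {}, {}, {}
    for scale in SCALES:
        cv = cv_from_summary(stats[f"{scale}_mean"].to_numpy(),
                             stats[f"{scale}_sd"].to_numpy())
        per_clip[scale] = cv
        mean_cv[scale] = float(cv.mean())
        sd_cv[scale] = float(cv.std(ddof=1))
    return CVSummary(per_clip, mean_cv, sd_cv)


def cv_summary_from_ratings(sam: pd.DataFrame) -> CVSummary:
    """CV summary per scale from individual ratings (long format with
    participant_id, clip_id and the three scale columns)."""
    per_clip, mean_cv, sd_cv = {}, {}, {}
    for scale in SCALES:
        cv = (sam.groupby("clip_id")[scale]
              .apply(lambda v: coefficient_of_variation(v.to_numpy()))
              .to_numpy())
        per_clip[scale] = cv
        mean_cv[scale] = float(cv.mean())
        sd_cv[scale] = float(cv.std(ddof=1))
    return CVSummary(per_clip, mean_cv, sd_cv)


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-aware Spearman rank correlation.

    Both lists are transformed to average ranks and the Pearson
    product-moment formula is applied to the rank variables, which handles
    the ties that discrete 1-9 ratings produce.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length inputs of at least 3 pairs")
    rx = rankdata(x, method="average")
    ry = rankdata(y, method="average")
    dx = rx - rx.mean()
    dy = ry - ry.mean()
    denom = np.sqrt((dx ** 2).sum() * (dy ** 2).sum())
    if denom == 0:
        raise ValueError("rank variance is zero (constant input)")
    return float((dx * dy).sum() / denom)


def spearman_pvalue(rho: float, n: int) -> float:
    """Two-sided t-approximation p-value for a Spearman coefficient."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(rho) >= 1.0:
        return 0.0
    t_stat = rho * np.sqrt((n - 2) / (1 - rho ** 2))
    return float(2 * t_dist.sf(abs(t_stat), df=n - 2))


QUADRANTS = ("LALV", "LAHV", "HALV", "HAHV")


def quadrant(valence: float, arousal: float, center: float = 5.0) -> str:
    """Valence-arousal quadrant label; coordinates equal to the center are
    assigned to the "low" half (boundary convention)."""
    if not (RATING_MIN <= valence <= RATING_MAX
            and RATING_MIN <= arousal <= RATING_MAX):
        raise ValueError("ratings must lie in [1, 9]")
    high_a = arousal > center
    high_v = valence > center
    return ("HA" if high_a else "LA") + ("HV" if high_v else "LV")


def binarize_labels(sam: pd.DataFrame,
                    threshold: int = LABEL_THRESHOLD) -> pd.DataFrame:
    """Threshold binarization of a long-format SAM table.

    Ratings below the threshold map to "low", above it to "high", and
    exactly at it to "excluded" (those trials carry no label). Returns a
    long frame with columns participant_id, clip_id, scale, label.
    """
    rows = []
    for _, rec in sam.iterrows():
        for scale in SCALES:
            rating = rec[scale]
            if rating < threshold:
                label = "low"
            elif rating > threshold:
                label = "high"
            else:
                label = "excluded"
            rows.append({"participant_id": rec["participant_id"],
                         "clip_id": rec["clip_id"],
                         "scale": scale, "label": label})
    return pd.DataFrame(rows)


def class_distribution(labels: pd.DataFrame,
                       windows_per_clip: int = 12) -> pd.DataFrame:
    """Window-level class counts per scale.

    Each labeled (non-excluded) trial contributes ``windows_per_clip``
    samples. Returns a frame indexed by scale with columns low, high,
    total and high_ratio (percent; NaN when no trial is labeled).
    """
    rows = []
    for scale in SCALES:
        sub = labels[labels["scale"] == scale]
        low = int((sub["label"] == "low").sum()) * windows_per_clip
        high = int((sub["label"] == "high").sum()) * windows_per_clip
        total = low + high
        ratio = 100.0 * high / total if total else float("nan")
        rows.append({"scale": scale, "low": low, "high": high,
                     "total": total, "high_ratio": ratio})
    return pd.DataFrame(rows).set_index("scale")


def high_ratio_from_counts(low: int, high: int) -> float:
    """Percentage of "high" samples among labeled samples."""
    total = low + high
    if total == 0:
        raise ValueError("no labeled samples")
    return 100.0 * high / total
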