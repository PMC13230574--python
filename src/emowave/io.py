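"""Readers and writers for every on-disk format the dataset defines.

Raw radar data live in level-5 MAT files holding a matrix "adcData" with
one row per virtual channel and chirp-sequential columns (the fast-time
samples of chirp j are followed by those of chirp j+1). PPG/GSR raw data
are two-column CSVs with two header rows (sampling frequency, channel
names); SAM ratings are per-participant four-column CSVs; feature files
hold a "featureMatrix" (windows x features). Numeric text is written
with shortest round-trip precision so write -> read is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.io

from .features import (FeatureMatrix, GSR_FEATURES, MMWAVE_FEATURES,
                       PPG_FEATURES)
from .physio import PhysioSignal
from .radar import AdcCube, RadarConfig, VitalSignBundle
from .ratings import N_CLIPS, RATING_MAX, RATING_MIN, SCALES

PHYSIO_FS = 200.0  # Hz, PPG/GSR sampling rate used by the recording device


@dataclass(frozen=True)
class TrialKey:
    """One (participant, clip) recording."""

    participant_id: str  # zero-padded two-digit identifier, "01"...
    clip_id: int  # 1..18

    def __post_init__(self) -> None:
        if (len(self.participant_id) != 2
                or not self.participant_id.isdigit()):
            raise ValueError("participant_id must be a zero-padded 2-digit string")
        if not 1 <= self.clip_id <= N_CLIPS:
            raise ValueError(f"clip_id must lie in [1, {N_CLIPS}]")


# ---------------------------------------------------------------------------
# dataset folder layout

def raw_adc_path(root: Path, key: TrialKey) -> Path:
    return Path(root) / "mmwave" / f"P{key.participant_id}" / f"{key.clip_id}.mat"


def raw_physio_path(root: Path, key: TrialKey) -> Path:
    return (Path(root) / "ppg_and_gsr" / f"P{key.participant_id}"
            / f"{key.clip_id}.csv")


def sam_path(root: Path, participant_id: str) -> Path:
    return Path(root) / "self_assessment" / "SAM" / f"SAM_P{participant_id}.csv"


def processed_mmwave_path(root: Path, key: TrialKey) -> Path:
    return (Path(root) / "mmwave"
            / f"mmwave_P{key.participant_id}_{key.clip_id:02d}.csv")


def processed_physio_path(root: Path, kind: str, key: TrialKey) -> Path:
    if kind not in ("ppg", "gsr"):
        raise ValueError("kind must be 'ppg' or 'gsr'")
    return (Path(root) / kind
            / f"{kind}_P{key.participant_id}_{key.clip_id:02d}.csv")


def feature_path(root: Path, kind: str, key: TrialKey) -> Path:
    if kind not in ("mmwave", "ppg", "gsr"):
        raise ValueError("kind must be 'mmwave', 'ppg' or 'gsr'")
    return (Path(root) / kind
            / f"{kind}Fea_P{key.participant_id}_{key.clip_id:02d}.mat")


# ---------------------------------------------------------------------------
# MAT files

def _load_mat_matrix(path: Path, name: str) -> np.ndarray:
    """Read a named matrix from a level-5 MAT file, falling back to the
    HDF5-based MAT dialect."""
    try:
        contents = scipy.io.loadmat(path)
        if name not in contents:
            raise KeyError(f"{path} contains no matrix named {name!r}")
        return np.asarray(contents[name])
    except NotImplementedError:  # MAT v7.3 (HDF5)
        with h5py.File(path, "r") as f:
            if name not in f:
                raise KeyError(f"{path} contains no matrix named {name!r}")
            data = f[name][()]
        if data.dtype.names and set(data.dtype.names) >= {"real", "imag"}:
            data = data["real"] + 1j * data["imag"]
        return data.T  # HDF5 MAT stores column-major


def write_adc_mat(path: Path, cube: AdcCube) -> None:
    """Write a cube as "adcData": channels x (samples * chirps), columns
    chirp-sequential."""
    flat = cube.data.transpose(0, 2, 1).reshape(cube.n_channels, -1)
    scipy.io.savemat(path, {"adcData": flat})


def read_adc_mat(path: Path, config: RadarConfig) -> AdcCube:
    """Read "adcData" and reshape the chirp-sequential rows into a cube.

    Validates that the row count equals Tx*Rx and the column count is an
    integral number of chirps; clip duration is inferred from the column
    count rather than trusted from the file name.
    """
    mat = _load_mat_matrix(Path(path), "adcData")
    if mat.ndim != 2:
        raise ValueError(f"adcData in {path} is not a 2-D matrix")
    n_ch = config.n_virtual_channels
    if mat.shape[0] != n_ch:
        raise ValueError(
            f"adcData has {mat.shape[0]} rows, expected Tx*Rx = {n_ch}")
    if mat.shape[1] % config.adc_samples != 0:
        raise ValueError(
            f"adcData column count {mat.shape[1]} is not divisible by "
            f"adc_samples = {config.adc_samples} (truncated file?)")
    n_chirps = mat.shape[1] // config.adc_samples
    cube = mat.reshape(n_ch, n_chirps, config.adc_samples).transpose(0, 2, 1)
    return AdcCube(cube)


def write_feature_matrix(path: Path, features: FeatureMatrix) -> None:
    """Write a feature matrix as "featureMatrix" (windows x features)."""
    if features.values.shape[0] == 0:
        raise ValueError("refusing to write an empty feature matrix")
    scipy.io.savemat(path, {"featureMatrix": features.values})


def read_feature_matrix(path: Path, signal_kind: str) -> FeatureMatrix:
    """Read "featureMatrix" and attach the fixed schema for ``signal_kind``."""
    mat = _load_mat_matrix(Path(path), "featureMatrix")
    schema = {"mmwave": MMWAVE_FEATURES, "ppg": PPG_FEATURES,
              "gsr": GSR_FEATURES}[signal_kind]
    return FeatureMatrix(np.real(mat), schema, signal_kind)


# ---------------------------------------------------------------------------
# CSV dialects

def _fmt(value: float) -> str:
    """Shortest decimal that round-trips the float exactly."""
    return repr(float(value))


def write_physio_csv(path: Path, ppg: PhysioSignal, gsr: PhysioSignal) -> None:
    """Two-column raw physiology CSV: row 1 sampling frequencies, row 2
    channel names, then PPG and GSR samples."""
    if ppg.samples.size != gsr.samples.size:
        raise ValueError("PPG and GSR must have equal length")
    if ppg.fs != gsr.fs:
        raise ValueError("PPG and GSR must share a sampling rate")
    with open(path, "w", newline="") as f:
        f.write(f"{_fmt(ppg.fs)},{_fmt(gsr.fs)}\n")
        f.write("PPG,GSR\n")
        for p, g in zip(ppg.samples, gsr.samples):
            f.write(f"{_fmt(p)},{_fmt(g)}\n")


def read_physio_csv(path: Path) -> tuple[PhysioSignal, PhysioSignal]:
    """Read the two-header-row physiology dialect.

    Row 1 carries the sampling frequency, row 2 the channel names (any
    text accepted); the first data column is PPG (a.u.), the second GSR
    resistance (kOhm).
    """
    with open(path) as f:
        header_fs = f.readline().strip()
        f.readline()  # channel-name row, content not enforced
        try:
            data = np.loadtxt(f, delimiter=",", ndmin=2)
        except ValueError as exc:
            raise ValueError(f"non-numeric data rows in {path}: {exc}") from exc
    try:
        fs = float(header_fs.split(",")[0])
    except ValueError as exc:
        raise ValueError(f"malformed sampling-frequency header in {path}") from exc
    if data.shape[1] != 2:
        raise ValueError(f"{path} has {data.shape[1]} columns, expected 2")
    return (PhysioSignal(data[:, 0], fs, "a.u."),
            PhysioSignal(data[:, 1], fs, "kohm"))


def write_sam_csv(path: Path, table: pd.DataFrame) -> None:
    """Write one participant's SAM ratings (clip_id, valence, arousal,
    dominance; one row per clip)."""
    _validate_sam(table)
    table[["clip_id", *SCALES]].astype(int).to_csv(path, index=False)


def read_sam_csv(path: Path) -> pd.DataFrame:
    """Read and validate one participant's SAM ratings."""
    table = pd.read_csv(path)
    expected = ["clip_id", *SCALES]
    if list(table.columns) != expected:
        raise ValueError(f"{path} columns {list(table.columns)} != {expected}")
    _validate_sam(table)
    return table.astype(int)


def _validate_sam(table: pd.DataFrame) -> None:
    for scale in SCALES:
        vals = table[scale].to_numpy()
        if not np.all((vals >= RATING_MIN) & (vals <= RATING_MAX)):
            raise ValueError(f"{scale} ratings outside [{RATING_MIN}, {RATING_MAX}]")
        if not np.all(vals == vals.astype(int)):
            raise ValueError(f"{scale} ratings must be integers")
    clips = table["clip_id"].to_numpy()
    if clips.size != np.unique(clips).size:
        raise ValueError("duplicate clip_id rows")


def write_processed_mmwave_csv(path: Path, bundle: VitalSignBundle) -> None:
    """Processed radar CSV: header row, then phase / respiration /
    heartbeat columns (phase column is the vital sign, aligned with the
    filtered series)."""
    with open(path, "w", newline="") as f:
        f.write("phase,respiration,heartbeat\n")
        for p, r, h in zip(bundle.vital_sign, bundle.respiration,
                           bundle.heartbeat):
            f.write(f"{_fmt(p)},{_fmt(r)},{_fmt(h)}\n")


def read_processed_mmwave_csv(path: Path, fs: float = 100.0) -> VitalSignBundle:
    data = pd.read_csv(path, float_precision="round_trip")
    expected = ["phase", "respiration", "heartbeat"]
    if list(data.columns) != expected:
        raise ValueError(f"{path} columns {list(data.columns)} != {expected}")
    vital = data["phase"].to_numpy()
    fused = np.concatenate([[0.0], np.cumsum(vital)])
    return VitalSignBundle(fused, vital, data["respiration"].to_numpy(),
                           data["heartbeat"].to_numpy(), fs)


def write_single_column_csv(path: Path, signal: PhysioSignal) -> None:
    """Processed PPG/GSR dialect: a single unlabeled column of samples."""
    with open(path, "w", newline="") as f:
        for v in signal.samples:
            f.write(f"{_fmt(v)}\n")


def read_single_column_csv(path: Path, fs: float, unit: str) -> PhysioSignal:
    data = np.loadtxt(path, ndmin=1)
    return PhysioSignal(data, fs, unit)


def read_participants_metadata(path: Path) -> pd.DataFrame:
    """Convenience parser for Participants_metadata.csv."""
    return pd.read_csv(path)
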