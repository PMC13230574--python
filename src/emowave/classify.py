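"""Subject-dependent binary emotion classification baseline.

Per participant and scale: trials with a definite low/high label are
split window-wise (first 75% of each trial's windows train, rest test),
Z-scored with training-set statistics only, and classified with an
RBF-kernel SVM whose (C, gamma) are chosen by stratified-CV grid search
over 11 x 6 log-spaced candidates. Reported metrics are accuracy,
balanced accuracy (mean per-class recall) and F1, in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (balanced_accuracy_score, confusion_matrix,
                             f1_score)
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

TRAIN_FRACTION = 0.75


@dataclass(frozen=True)
class GridSpec:
    """RBF-SVM hyperparameter grid: C in 10^-5..10^5 (11 values), gamma in
    10^-4..10 (6 values), both geometric."""

    c_values: tuple[float, ...] = tuple(np.logspace(-5, 5, 11))
    gamma_values: tuple[float, ...] = tuple(np.logspace(-4, 1, 6))

    @property
    def n_candidates(self) -> int:
        return len(self.c_values) * len(self.gamma_values)


@dataclass
class SplitDataset:
    """Train/test feature rows with (participant, clip, window) provenance."""

    x_train: np.ndarray
    y_train: np.ndarray
    x_test: np.ndarray
    y_test: np.ndarray
    train_provenance: list[tuple[str, int, int]] = field(default_factory=list)
    test_provenance: list[tuple[str, int, int]] = field(default_factory=list)


@dataclass
class EvalReport:
    """Test-set metrics in percent plus raw confusion counts
    (rows true, columns predicted, order low/high)."""

    accuracy: float
    balanced_accuracy: float
    f1_high: float
    f1_macro: float
    recall_low: float
    recall_high: float
    confusion: np.ndarray


def split_by_trial(trials: list[tuple[str, int, np.ndarray, str]],
                   fraction: float = TRAIN_FRACTION) -> SplitDataset:
    """Window-wise temporal split of labeled trials.

    ``trials`` holds (participant_id, clip_id, windows-x-features matrix,
    label) tuples; "excluded" labels are dropped. Within each remaining
    trial the first ceil(fraction * n) windows (temporal order) go to the
    training set, the rest to the test set.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    xtr, ytr, xte, yte = [], [], [], []
    prov_tr, prov_te = [], []
    for participant, clip, matrix, label in trials:
        if label == "excluded":
            continue
        if label not in ("low", "high"):
            raise ValueError(f"unknown label {label!r}")
        matrix = np.atleast_2d(matrix)
        n = matrix.shape[0]
        if n < 4:
            raise ValueError(f"trial {participant}/{clip} has {n} windows (<4)")
        n_train = int(np.ceil(fraction * n))
        if n_train >= n:
            raise ValueError("split leaves an empty test set")
        for w in range(n):
            (xtr if w < n_train else xte).append(matrix[w])
            (ytr if w < n_train else yte).append(label)
            (prov_tr if w < n_train else prov_te).append((participant, clip, w))
    if not xtr:
        raise ValueError("no labeled trials to split")
    return SplitDataset(np.vstack(xtr), np.array(ytr),
                        np.vstack(xte), np.array(yte), prov_tr, prov_te)


def zscore_fit_apply(split: SplitDataset) -> SplitDataset:
    """Standardize features with training-set mean/SD only.

    Training columns come out with mean 0 and SD 1; test rows are mapped
    with the same statistics (no leakage). Zero-SD features are set to 0.
    """
    mean = split.x_train.mean(axis=0)
    sd = split.x_train.std(axis=0)
    safe = np.where(sd == 0, 1.0, sd)
    xtr = (split.x_train - mean) / safe
    xte = (split.x_test - mean) / safe
    zero = sd == 0
    xtr[:, zero] = 0.0
    xte[:, zero] = 0.0
    return SplitDataset(xtr, split.y_train.copy(), xte, split.y_test.copy(),
                        list(split.train_provenance),
                        list(split.test_provenance))


def grid_search_svm(x_train: np.ndarray, y_train: np.ndarray,
                    grid: GridSpec = GridSpec(), cv_folds: int = 5,
                    seed: int = 0) -> GridSearchCV:
    """Stratified-CV grid search over the 66 (C, gamma) candidates.

    The best pair by CV accuracy is refit on the full training set;
    deterministic under ``seed`` (fold shuffling is the only randomness).
    """
    classes, counts = np.unique(y_train, return_counts=True)
    if classes.size < 2:
        raise ValueError("training set contains a single class")
    folds = min(cv_folds, int(counts.min()))
    if folds < 2:
        raise ValueError("too few samples in the minority class for CV")
    search = GridSearchCV(
        SVC(kernel="rbf"),
        {"C": list(grid.c_values), "gamma": list(grid.gamma_values)},
        cv=StratifiedKFold(folds, shuffle=True, random_state=seed),
        scoring="accuracy",
        n_jobs=1,
    )
    search.fit(x_train, y_train)
    return search


def evaluate(model, x_test: np.ndarray, y_test: np.ndarray) -> EvalReport:
    """Accuracy, balanced accuracy, F1 (high class and macro) in percent."""
    if len(y_test) == 0:
        raise ValueError("empty test set")
    pred = model.predict(x_test)
    labels = ["low", "high"]
    conf = confusion_matrix(y_test, pred, labels=labels)
    with np.errstate(invalid="ignore"):
        recalls = np.where(conf.sum(axis=1) > 0,
                           np.diag(conf) / conf.sum(axis=1), 0.0)
    return EvalReport(
        accuracy=100.0 * float(np.mean(pred == y_test)),
        balanced_accuracy=100.0 * float(
            balanced_accuracy_score(y_test, pred)),
        f1_high=100.0 * float(f1_score(y_test, pred, pos_label="high",
                                       labels=labels, zero_division=0)),
        f1_macro=100.0 * float(f1_score(y_test, pred, average="macro",
                                        labels=labels, zero_division=0)),
        recall_low=100.0 * float(recalls[0]),
        recall_high=100.0 * float(recalls[1]),
        confusion=conf,
    )


def run_subject_dependent(trials: list[tuple[str, int, np.ndarray, str]],
                          grid: GridSpec = GridSpec(), seed: int = 0
                          ) -> EvalReport:
    """Full baseline for one participant/scale: split, Z-score, grid-search
    SVM, evaluate."""
    split = zscore_fit_apply(split_by_trial(trials))
    model = grid_search_svm(split.x_train, split.y_train, grid=grid, seed=seed)
    return evaluate(model, split.x_test, split.y_test)
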