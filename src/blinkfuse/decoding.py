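"""Sliding-window linear-SVM decoding and temporal generalization.

Features are assembled per 50 ms window (13 samples at 250 Hz) by flattening
series x in-window samples per trial; classes are balanced by downsampling
the majority class; each window is decoded with a five-repetition stratified
80/20 split, z-scoring with train-set parameters only, and a linear SVM.
Performance is reported as accuracy, sensitivity and specificity in percent,

    Acc = (TP + TN) / (TN + TP + FP + FN) * 100
    Sen = TP / (FN + TP) * 100
    Spe = TN / (FP + TN) * 100

macro-averaged over one-vs-rest class counts for multi-class problems.  The
temporal generalization matrix trains at one window and tests at every
other, on the same folds and with the training window's normalization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC

from .blink_extraction import EpochSet
from .fusion import FusedEpochSet

logger = logging.getLogger("blinkfuse")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Flattened window features: n_features x n_trials."""

    features: np.ndarray
    window_center_ms: float
    window_samples: int
    labels: np.ndarray
    source_blocks: dict[str, tuple[int, ...]] | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.features)):
            raise ValueError("feature matrix contains non-finite values")
        if self.labels.shape != (self.features.shape[1],):
            raise ValueError("labels length must equal n_trials")

    @property
    def n_features(self) -> int:
        return self.features.shape[0]

    @property
    def n_trials(self) -> int:
        return self.features.shape[1]


@dataclass
class ConfusionCounts:
    """Binary (or pooled one-vs-rest) confusion counts."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.TN + other.TN,
                               self.FP + other.FP, self.FN + other.FN)


@dataclass
class Metrics:
    """Acc/Sen/Spe in percent; undefined entries are NaN with a flag."""

    acc: float
    sen: float
    spe: float
    sen_undefined: bool = False
    spe_undefined: bool = False


@dataclass
class WindowScore:
    """Mean decoding metrics at one window over CV repetitions."""

    window_center_ms: float
    acc: float
    sen: float
    spe: float
    acc_per_rep: np.ndarray
    sen_per_rep: np.ndarray
    spe_per_rep: np.ndarray


@dataclass
class DecodingCurve:
    """Per-window decoding time course for one participant/method."""

    window_centers_ms: np.ndarray
    acc: np.ndarray
    sen: np.ndarray
    spe: np.ndarray
    chance_level: float
    acc_per_rep: np.ndarray = None   # n_windows x n_reps
    participant_id: str = "sub-01"
    method: str = ""

    @property
    def peak_acc(self) -> float:
        return float(np.nanmax(self.acc))

    @property
    def peak_time_ms(self) -> float:
        return float(self.window_centers_ms[int(np.nanargmax(self.acc))])


@dataclass
class TemporalGeneralizationMatrix:
    """Train-window x test-window accuracy (%) grid."""

    scores: np.ndarray
    train_centers_ms: np.ndarray
    test_centers_ms: np.ndarray
    chance_level: float
    participant_id: str = "sub-01"
    method: str = ""


# ---------------------------------------------------------------------------
# Window assembly
# ---------------------------------------------------------------------------

def window_length_samples(window_ms: float, fs: float) -> int:
    """Sample count of the moving window: ceil(ms·fs/1000) rounded up to odd."""
    w = math.ceil(window_ms * fs / 1000.0)
    return w + 1 if w % 2 == 0 else w


def _epoch_array(obj: EpochSet | FusedEpochSet):
    if isinstance(obj, FusedEpochSet):
        return obj.fused_epochs, obj.time_ms, obj.fs, obj.labels, obj.component_blocks
    return obj.epochs, obj.time_ms, obj.fs, obj.labels, None


def slide_windows(
    fused: EpochSet | FusedEpochSet,
    window_ms: float = 50.0,
    step_samples: int = 1,
):
    """Yield a FeatureMatrix per window position (series·samples x trials)."""
    data, time_ms, fs, labels, blocks = _epoch_array(fused)
    n_ep, n_series, n_t = data.shape
    w = window_length_samples(window_ms, fs)
    if w > n_t:
        raise ValueError("window longer than the epoch")
    if labels is None:
        raise ValueError("labels are required for decoding")

    for start in range(0, n_t - w + 1, step_samples):
        feats = data[:, :, start:start + w].reshape(n_ep, n_series * w).T
        center = float(time_ms[start + w // 2])
        yield FeatureMatrix(
            features=feats, window_center_ms=center, window_samples=w,
            labels=labels, source_blocks=blocks,
        )


def n_window_positions(n_times: int, window_samples: int, step_samples: int = 1) -> int:
    return (n_times - window_samples) // step_samples + 1


# ---------------------------------------------------------------------------
# Class balancing
# ---------------------------------------------------------------------------

def balance_classes(labels: np.ndarray, seed: int) -> np.ndarray:
    """Downsample every majority class to the minority count (sorted indices)."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    if counts.min() == 0:
        raise ValueError("a class is empty")
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    kept: list[np.ndarray] = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        if idx.size > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        kept.append(idx)
    return np.sort(np.concatenate(kept))


def pool_rest(labels: np.ndarray, positive: str,
              rest_label: str = "rest") -> np.ndarray:
    """Relabel for one-vs-rest decoding: everything but ``positive`` pools."""
    labels = np.asarray(labels)
    return np.where(labels == positive, labels, rest_label).astype(object)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def evaluate_metrics(c: ConfusionCounts) -> Metrics:
    """Acc/Sen/Spe percentages from confusion counts; undefined → NaN + flag."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    acc = 100.0 * (c.TP + c.TN) / c.total
    sen_undef = (c.TP + c.FN) == 0
    spe_undef = (c.TN + c.FP) == 0
    sen = math.nan if sen_undef else 100.0 * c.TP / (c.FN + c.TP)
    spe = math.nan if spe_undef else 100.0 * c.TN / (c.FP + c.TN)
    if sen_undef or spe_undef:
        logger.warning("evaluate_metrics: undefined metric (no positives or negatives)")
    return Metrics(acc=acc, sen=sen, spe=spe,
                   sen_undefined=sen_undef, spe_undefined=spe_undef)


def ovr_counts(y_true: np.ndarray, y_pred: np.ndarray,
               positive) -> ConfusionCounts:
    """One-vs-rest confusion counts for a single positive class."""
    tp = int(np.sum((y_true == positive) & (y_pred == positive)))
    fn = int(np.sum((y_true == positive) & (y_pred != positive)))
    fp = int(np.sum((y_true != positive) & (y_pred == positive)))
    tn = int(np.sum((y_true != positive) & (y_pred != positive)))
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def _macro_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                   classes: np.ndarray) -> tuple[float, float, float]:
    """Accuracy plus macro-averaged one-vs-rest Sen/Spe, in percent."""
    acc = 100.0 * float(np.mean(y_true == y_pred))
    sens, spes = [], []
    for c in classes:
        m = evaluate_metrics(ovr_counts(y_true, y_pred, c))
        if not m.sen_undefined:
            sens.append(m.sen)
        if not m.spe_undefined:
            spes.append(m.spe)
    return acc, float(np.mean(sens)) if sens else math.nan, \
        float(np.mean(spes)) if spes else math.nan


# ---------------------------------------------------------------------------
# Cross-validated decoding
# ---------------------------------------------------------------------------

def make_splits(labels: np.ndarray, repetitions: int = 5,
                test_frac: float = 0.20, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified random 80/20 splits shared across methods/windows."""
    sss = StratifiedShuffleSplit(n_splits=repetitions, test_size=test_frac,
                                 random_state=seed % (2 ** 31))
    dummy = np.zeros((labels.size, 1))
    return [(tr.copy(), te.copy()) for tr, te in sss.split(dummy, labels)]


class _TrainScaler:
    """Z-scoring with train-set parameters; zero-SD features get scale 1."""

    def __init__(self, train_feats: np.ndarray):
        # train_feats: n_trials x n_features
        self.mean = train_feats.mean(axis=0)
        sd = train_feats.std(axis=0)
        n_flat = int(np.sum(sd == 0))
        if n_flat:
            logger.info("z-scoring: %d zero-variance features, scale set to 1", n_flat)
        self.scale = np.where(sd > 0, sd, 1.0)

    def __call__(self, feats: np.ndarray) -> np.ndarray:
        return (feats - self.mean) / self.scale


def _make_svm(n_classes: int, C: float):
    svm = SVC(kernel="linear", C=C)
    return OneVsRestClassifier(svm) if n_classes > 2 else svm


def cross_validated_decode(
    fm: FeatureMatrix,
    repetitions: int = 5,
    test_frac: float = 0.20,
    seed: int = 0,
    C: float = 1.0,
    splits: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> WindowScore:
    """Balanced-label linear-SVM decoding at one window position.

    Per repetition: stratified 80/20 split, z-score with train statistics,
    fit a linear SVM (one-vs-rest ensemble for >2 classes), pool one-vs-rest
    confusion counts on the test set.  Pre-drawn ``splits`` may be supplied
    so several methods are evaluated on identical folds.
    """
    if fm.n_trials < 10:
        raise ValueError("need at least 10 trials")
    classes = np.unique(fm.labels)
    if splits is None:
        splits = make_splits(fm.labels, repetitions, test_frac, seed)

    X = fm.features.T  # trials x features
    accs, sens, spes = [], [], []
    for tr, te in splits:
        scaler = _TrainScaler(X[tr])
        clf = _make_svm(classes.size, C)
        clf.fit(scaler(X[tr]), fm.labels[tr])
        y_pred = clf.predict(scaler(X[te]))
        a, s, p = _macro_metrics(fm.labels[te], y_pred, classes)
        accs.append(a), sens.append(s), spes.append(p)

    accs, sens, spes = map(np.asarray, (accs, sens, spes))
    return WindowScore(
        window_center_ms=fm.window_center_ms,
        acc=float(np.nanmean(accs)), sen=float(np.nanmean(sens)),
        spe=float(np.nanmean(spes)),
        acc_per_rep=accs, sen_per_rep=sens, spe_per_rep=spes,
    )


def decode_timecourse(
    fused: EpochSet | FusedEpochSet,
    window_ms: float = 50.0,
    step_samples: int = 1,
    repetitions: int = 5,
    test_frac: float = 0.20,
    seed: int = 0,
    C: float = 1.0,
    splits: list[tuple[np.ndarray, np.ndarray]] | None = None,
    method: str = "",
) -> DecodingCurve:
    """Run cross-validated decoding at every window position."""
    _, _, _, labels, _ = _epoch_array(fused)
    classes = np.unique(labels)
    if splits is None:
        splits = make_splits(labels, repetitions, test_frac, seed)
    scores = [cross_validated_decode(fm, repetitions, test_frac, seed, C, splits)
              for fm in slide_windows(fused, window_ms, step_samples)]
    pid = getattr(fused, "participant_id", "sub-01")
    return DecodingCurve(
        window_centers_ms=np.asarray([s.window_center_ms for s in scores]),
        acc=np.asarray([s.acc for s in scores]),
        sen=np.asarray([s.sen for s in scores]),
        spe=np.asarray([s.spe for s in scores]),
        chance_level=100.0 / classes.size,
        acc_per_rep=np.stack([s.acc_per_rep for s in scores]),
        participant_id=pid, method=method,
    )


def temporal_generalization(
    fused: EpochSet | FusedEpochSet,
    window_ms: float = 50.0,
    step_samples: int = 1,
    repetitions: int = 5,
    test_frac: float = 0.20,
    seed: int = 0,
    C: float = 1.0,
    splits: list[tuple[np.ndarray, np.ndarray]] | None = None,
    method: str = "",
) -> TemporalGeneralizationMatrix:
    """Train at each window, test at every window, on shared folds.

    Test-window features are normalized with the training window's
    train-fold statistics, so the diagonal reproduces the decoding time
    course computed with identical folds and seed exactly.
    """
    data, time_ms, fs, labels, _ = _epoch_array(fused)
    classes = np.unique(labels)
    if splits is None:
        splits = make_splits(labels, repetitions, test_frac, seed)

    mats = list(slide_windows(fused, window_ms, step_samples))
    centers = np.asarray([fm.window_center_ms for fm in mats])
    feats = [fm.features.T for fm in mats]          # trials x features each
    n_w = len(mats)
    scores = np.zeros((n_w, n_w))

    for tr, te in splits:
        y_tr, y_te = labels[tr], labels[te]
        for i in range(n_w):
            scaler = _TrainScaler(feats[i][tr])
            clf = _make_svm(classes.size, C)
            clf.fit(scaler(feats[i][tr]), y_tr)
            for j in range(n_w):
                y_pred = clf.predict(scaler(feats[j][te]))
                scores[i, j] += 100.0 * float(np.mean(y_pred == y_te))
    scores /= len(splits)

    pid = getattr(fused, "participant_id", "sub-01")
    return TemporalGeneralizationMatrix(
        scores=scores, train_centers_ms=centers, test_centers_ms=centers.copy(),
        chance_level=100.0 / classes.size, participant_id=pid, method=method,
    )


def bootstrap_ci(per_participant: np.ndarray, n_boot: int = 1000,
                 seed: int = 0, ci: float = 95.0) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap CI of the across-participant mean curve (participants x points)."""
    x = np.atleast_2d(np.asarray(per_participant, dtype=float))
    rng = np.random.default_rng(seed)
    n_p = x.shape[0]
    idx = rng.integers(0, n_p, size=(n_boot, n_p))
    boots = x[idx].mean(axis=1)
    lo = np.percentile(boots, (100 - ci) / 2, axis=0)
    hi = np.percentile(boots, 100 - (100 - ci) / 2, axis=0)
    return lo, hi
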