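"""Blink-component identification, blink detection, epoching and epoch rejection.

The entry point of the analysis is a continuous multichannel EEG recording
plus a linear component decomposition (user-supplied unmixing matrix, a
ground-truth matrix on simulations, or one fitted with FastICA).  This module
locates the blink component among the flagged eye candidates, detects blink
peaks with a mean + 1.5 SD threshold rule, cuts epochs from -500 ms to
+1000 ms around each blink peak, and iteratively rejects artifact epochs
(500 µV absolute / 5 SD-z thresholds, at most 10 % of epochs per iteration).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.signal
from scipy.stats import pearsonr

logger = logging.getLogger("blinkfuse")

#: 30-electrode 10-20 montage used by the simulator and as a default layout.
MONTAGE_30 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FT7", "FC3", "FCz", "FC4", "FT8",
    "T7", "C3", "Cz", "C4", "T8",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
)


class UnrecoverableRecordingError(RuntimeError):
    """All channels were flagged as bad during preprocessing."""


class NoBlinkComponentError(RuntimeError):
    """No eye candidate shows a positive left/right anterior correlation."""


class EmptyEpochSetError(RuntimeError):
    """An operation produced or received an epoch set with zero epochs."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ContinuousRecording:
    """Continuous EEG, channels x samples in µV."""

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...] = MONTAGE_30
    participant_id: str = "sub-01"
    bad_channels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 channels")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_index(self, label: str) -> int:
        return self.channel_labels.index(label)


@dataclass
class ComponentDecomposition:
    """Linear decomposition: activations = unmixing @ data.

    ``mixing @ unmixing`` must be the identity on the retained subspace; the
    eye-candidate flags may come from simulation ground truth, a label file,
    or :func:`flag_frontal_components`.
    """

    unmixing: np.ndarray            # components x channels
    mixing: np.ndarray              # channels x components
    activations: np.ndarray         # components x samples
    eye_candidate_flags: np.ndarray  # bool per component

    def __post_init__(self) -> None:
        self.unmixing = np.asarray(self.unmixing, dtype=float)
        self.mixing = np.asarray(self.mixing, dtype=float)
        self.activations = np.asarray(self.activations, dtype=float)
        self.eye_candidate_flags = np.asarray(self.eye_candidate_flags, dtype=bool)
        k = self.unmixing.shape[0]
        if self.mixing.shape[1] != k or self.activations.shape[0] != k:
            raise ValueError("inconsistent component counts")
        if self.eye_candidate_flags.shape != (k,):
            raise ValueError("eye_candidate_flags must have one entry per component")
        # identity on the retained subspace, relative tolerance 1e-6
        proj = self.unmixing @ self.mixing
        if not np.allclose(proj, np.eye(k), atol=1e-6 * max(1.0, np.abs(proj).max())):
            raise ValueError("mixing @ unmixing is not identity on the retained subspace")

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]


@dataclass
class BlinkEventSeries:
    """Detected blink maxima (sample indices) for one recording."""

    peak_samples: np.ndarray
    component_index: int
    threshold_used: float

    def __post_init__(self) -> None:
        self.peak_samples = np.asarray(self.peak_samples, dtype=int)
        if self.peak_samples.size and np.any(np.diff(self.peak_samples) <= 0):
            raise ValueError("peak_samples must be strictly increasing")

    def __len__(self) -> int:
        return int(self.peak_samples.size)


@dataclass
class EpochSet:
    """Blink-locked epochs: n_epochs x n_series x n_times.

    ``series_kind`` records whether the rows are scalp channels, decomposition
    components, a single blink trace, or already-fused feature series.
    """

    epochs: np.ndarray
    time_ms: np.ndarray
    fs: float
    series_kind: str = "channels"
    labels: np.ndarray | None = None
    series_names: tuple[str, ...] | None = None
    participant_id: str = "sub-01"

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (epochs x series x times)")
        if self.time_ms.shape != (self.epochs.shape[2],):
            raise ValueError("time_ms length must match the time axis")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (self.epochs.shape[0],):
                raise ValueError("labels length must match n_epochs")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_series(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_times(self) -> int:
        return self.epochs.shape[2]

    def select(self, idx: np.ndarray) -> "EpochSet":
        """Return a copy restricted to the given epoch indices."""
        labels = None if self.labels is None else self.labels[idx]
        return replace(self, epochs=self.epochs[idx], labels=labels)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess(
    raw: ContinuousRecording,
    highpass_hz: float = 0.1,
    lowpass_hz: float = 40.0,
    target_fs: float = 250.0,
    flatline_s: float = 0.5,
    correlation_threshold: float = 0.8,
) -> ContinuousRecording:
    """Band-pass filter, resample, flag bad channels, and re-reference.

    Zero-phase FIR band-pass (0.1--40 Hz default), polyphase resampling to
    ``target_fs``, flatline (> ``flatline_s`` constant) and low-correlation
    (to the leave-one-out channel mean) flagging, then common-average
    reference computed over unflagged channels.  Flagged channels are kept in
    the data but listed in ``bad_channels`` so the caller can drop or
    interpolate them.
    """
    import mne.filter

    if target_fs > raw.fs:
        raise ValueError("target_fs must not exceed the recording rate")
    nyq = raw.fs / 2.0
    if lowpass_hz >= nyq:
        raise ValueError("low-pass cutoff must be below Nyquist")

    # flatline check runs on the unfiltered data: filtering smears a
    # constant stretch into numerically non-constant values
    bad = set()
    for ch in range(raw.n_channels):
        if _longest_constant_run(raw.data[ch]) > int(round(flatline_s * raw.fs)):
            bad.add(raw.channel_labels[ch])

    # 5 Hz upper transition band keeps 50 Hz line frequency well inside the
    # stop band of the default 0.1–40 Hz pass band
    data = mne.filter.filter_data(
        raw.data, sfreq=raw.fs, l_freq=highpass_hz, h_freq=lowpass_hz,
        h_trans_bandwidth=min(5.0, max(nyq - lowpass_hz, 1.0)),
        method="fir", phase="zero", verbose=False,
    )

    if target_fs < raw.fs:
        from fractions import Fraction
        frac = Fraction(target_fs / raw.fs).limit_denominator(1000)
        data = scipy.signal.resample_poly(data, frac.numerator, frac.denominator, axis=1)
    fs = float(target_fs)

    # correlation to the mean of all other channels (leave-one-out)
    total = data.sum(axis=0)
    n_ch = data.shape[0]
    for ch in range(n_ch):
        others = (total - data[ch]) / (n_ch - 1)
        sd_a, sd_b = data[ch].std(), others.std()
        r = 0.0 if sd_a == 0 or sd_b == 0 else float(np.corrcoef(data[ch], others)[0, 1])
        if r < correlation_threshold:
            bad.add(raw.channel_labels[ch])

    if len(bad) == raw.n_channels:
        raise UnrecoverableRecordingError("all channels flagged as bad")

    good = [i for i, lab in enumerate(raw.channel_labels) if lab not in bad]
    data = data - data[good].mean(axis=0, keepdims=True)

    if bad:
        logger.info("preprocess: flagged %d bad channels: %s", len(bad), sorted(bad))
    return ContinuousRecording(
        data=data, fs=fs, channel_labels=raw.channel_labels,
        participant_id=raw.participant_id, bad_channels=tuple(sorted(bad)),
    )


def _longest_constant_run(x: np.ndarray) -> int:
    """Length (in samples) of the longest run of identical consecutive values."""
    if x.size == 0:
        return 0
    change = np.flatnonzero(np.diff(x) != 0)
    edges = np.concatenate(([-1], change, [x.size - 1]))
    return int(np.max(np.diff(edges)))


# ---------------------------------------------------------------------------
# Blink component identification
# ---------------------------------------------------------------------------

def identify_blink_component(
    decomp: ComponentDecomposition,
    left_anterior: int,
    right_anterior: int,
) -> int:
    """Pick the blink component among the eye candidates.

    Each candidate is back-projected onto the left and right anterior
    channels; the Pearson correlation between the two projected series is
    positive for a blink-like component (same-sign weights on both anterior
    sites) and negative for a horizontal-saccade-like component (opposite
    signs).  Returns the candidate with the largest positive correlation;
    ties are broken by anterior back-projected power.
    """
    candidates = np.flatnonzero(decomp.eye_candidate_flags)
    if candidates.size == 0:
        raise NoBlinkComponentError("no eye-candidate components flagged")

    best_idx, best_r, best_power = -1, -np.inf, -np.inf
    for c in candidates:
        left = decomp.mixing[left_anterior, c] * decomp.activations[c]
        right = decomp.mixing[right_anterior, c] * decomp.activations[c]
        if left.std() == 0 or right.std() == 0:
            continue
        r = float(pearsonr(left, right)[0])
        power = float(left @ left + right @ right)
        if r > best_r + 1e-12 or (abs(r - best_r) <= 1e-12 and power > best_power):
            best_idx, best_r, best_power = int(c), r, power

    if best_r <= 0:
        raise NoBlinkComponentError(
            "no eye candidate with positive left/right anterior correlation"
        )
    return best_idx


def flag_frontal_components(decomp_mixing: np.ndarray,
                            anterior_rows: tuple[int, ...],
                            dominance: float = 2.0) -> np.ndarray:
    """Heuristic eye-candidate flags: anterior mixing weights dominate.

    A component is flagged when its mean absolute weight over the anterior
    rows exceeds ``dominance`` times its mean absolute weight elsewhere.
    """
    mixing = np.asarray(decomp_mixing, dtype=float)
    rows = np.zeros(mixing.shape[0], dtype=bool)
    rows[list(anterior_rows)] = True
    front = np.abs(mixing[rows]).mean(axis=0)
    rest = np.abs(mixing[~rows]).mean(axis=0)
    return front > dominance * np.maximum(rest, 1e-30)


# ---------------------------------------------------------------------------
# Blink detection
# ---------------------------------------------------------------------------

def detect_blinks(
    blink_signal: np.ndarray,
    fs: float,
    sd_multiplier: float = 1.5,
    component_index: int = 0,
    min_duration_ms: float = 50.0,
    refractory_ms: float = 200.0,
) -> BlinkEventSeries:
    """Threshold-based blink peak detection on a component activation.

    The threshold is mean + ``sd_multiplier`` * SD of the whole signal; each
    contiguous supra-threshold interval longer than ``min_duration_ms``
    contributes one event at its maximum sample.  Events closer than
    ``refractory_ms`` are merged (the larger peak wins) so a noisy pulse is
    not double counted.  A zero-variance signal yields zero events.
    """
    x = np.asarray(blink_signal, dtype=float)
    if x.size == 0:
        raise ValueError("empty blink signal")
    if not np.all(np.isfinite(x)):
        raise ValueError("blink signal contains non-finite values")

    sd = x.std()
    threshold = float(x.mean() + sd_multiplier * sd)
    if sd == 0:
        return BlinkEventSeries(np.empty(0, dtype=int), component_index, threshold)

    above = x > threshold
    if not above.any():
        return BlinkEventSeries(np.empty(0, dtype=int), component_index, threshold)

    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    stops = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        stops = np.concatenate((stops, [x.size]))

    min_len = int(round(min_duration_ms * fs / 1000.0))
    peaks: list[int] = []
    for s, e in zip(starts, stops):
        if e - s < min_len:
            continue
        peaks.append(int(s + np.argmax(x[s:e])))

    # refractory merge: keep the larger of two peaks closer than refractory_ms
    gap = int(round(refractory_ms * fs / 1000.0))
    merged: list[int] = []
    for p in peaks:
        if merged and p - merged[-1] < gap:
            if x[p] > x[merged[-1]]:
                merged[-1] = p
        else:
            merged.append(p)

    return BlinkEventSeries(np.asarray(merged, dtype=int), component_index, threshold)


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------

def epoch_blink_locked(
    series: np.ndarray,
    fs: float,
    events: BlinkEventSeries | np.ndarray,
    window_ms: tuple[float, float] = (-500.0, 1000.0),
    labels: np.ndarray | None = None,
    series_kind: str = "channels",
    series_names: tuple[str, ...] | None = None,
    participant_id: str = "sub-01",
) -> EpochSet:
    """Cut blink-locked epochs with inclusive endpoints on the sample grid.

    ``series`` is a channels-or-components x samples array (a 1-D array is
    treated as a single series).  Events whose window would run past either
    end of the recording are dropped with a logged count; their labels are
    dropped consistently.
    """
    data = np.atleast_2d(np.asarray(series, dtype=float))
    peaks = events.peak_samples if isinstance(events, BlinkEventSeries) else np.asarray(events, dtype=int)
    lo = int(round(window_ms[0] * fs / 1000.0))
    hi = int(round(window_ms[1] * fs / 1000.0))
    n_t = hi - lo + 1

    keep = (peaks + lo >= 0) & (peaks + hi < data.shape[1])
    dropped = int((~keep).sum())
    if dropped:
        logger.info("epoch_blink_locked: dropped %d out-of-bounds events", dropped)
    retained = peaks[keep]
    if retained.size == 0:
        raise EmptyEpochSetError("no events with a full epoch window in bounds")

    epochs = np.stack([data[:, p + lo: p + hi + 1] for p in retained])
    time_ms = (np.arange(lo, hi + 1) / fs) * 1000.0
    kept_labels = None if labels is None else np.asarray(labels)[keep]
    return EpochSet(
        epochs=epochs, time_ms=time_ms, fs=fs, series_kind=series_kind,
        labels=kept_labels, series_names=series_names, participant_id=participant_id,
    )


# ---------------------------------------------------------------------------
# Iterative epoch rejection
# ---------------------------------------------------------------------------

@dataclass
class RejectionLog:
    """Per-iteration record of rejected epoch indices (original numbering)."""

    iterations: list[list[int]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return sum(len(it) for it in self.iterations)


def reject_epochs(
    epochs: EpochSet,
    abs_uv: float = 500.0,
    sd_thresh: float = 5.0,
    max_frac_per_iter: float = 0.10,
) -> tuple[EpochSet, RejectionLog]:
    """Iteratively discard artifact epochs.

    An epoch violates when its maximum absolute amplitude exceeds ``abs_uv``
    µV, or when the z-score of its per-series SD against the across-epoch SD
    distribution exceeds ``sd_thresh`` for any series.  Per iteration at most
    ``floor(max_frac_per_iter * current_n)`` epochs (minimum 1 while any
    violate) are removed, worst offenders first; iteration stops when no
    epoch violates.  The scoring is recomputed each iteration, so the
    procedure is idempotent once converged.
    """
    if epochs.n_epochs == 0:
        raise EmptyEpochSetError("cannot reject from an empty epoch set")

    keep = np.arange(epochs.n_epochs)
    data = epochs.epochs
    log = RejectionLog()

    while True:
        n = keep.size
        cur = data[keep]
        amp = np.abs(cur).max(axis=(1, 2))                      # per epoch
        ep_sd = cur.std(axis=2)                                 # epochs x series
        mu = ep_sd.mean(axis=0, keepdims=True)
        sigma = ep_sd.std(axis=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(sigma > 0, (ep_sd - mu) / sigma, 0.0)
        zmax = z.max(axis=1)

        violates = (amp > abs_uv) | (zmax > sd_thresh)
        if not violates.any():
            break

        cap = max(1, int(np.floor(max_frac_per_iter * n)))
        severity = np.maximum(amp / abs_uv, zmax / sd_thresh)
        offenders = np.flatnonzero(violates)
        offenders = offenders[np.argsort(severity[offenders])[::-1]][:cap]
        log.iterations.append(sorted(int(keep[i]) for i in offenders))
        keep = np.delete(keep, offenders)
        if keep.size == 0:
            raise EmptyEpochSetError("all epochs rejected")

    return epochs.select(keep), log
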