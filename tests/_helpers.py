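"""Shared test utilities: oracle solvers and canned study configurations."""

from __future__ import annotations

import numpy as np
import scipy.linalg

import blinkfuse as bf


def cca_oracle(X: np.ndarray, B: np.ndarray, ridge: float = 1e-8):
    """Whitening + SVD canonical correlation, independent of the package route.

    X, B are samples x channels.  Returns (rhos, U, V) with the same
    normalization and sign conventions as :func:`blinkfuse.fit_cca`.
    """
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    Bc = B - B.mean(axis=0)
    Sxx = Xc.T @ Xc / n
    Sbb = Bc.T @ Bc / n
    Sxb = Xc.T @ Bc / n
    Sxx = Sxx + ridge * np.trace(Sxx) / Sxx.shape[0] * np.eye(Sxx.shape[0])
    Sbb = Sbb + ridge * np.trace(Sbb) / Sbb.shape[0] * np.eye(Sbb.shape[0])
    Wx = scipy.linalg.inv(scipy.linalg.sqrtm(Sxx).real)
    Wb = scipy.linalg.inv(scipy.linalg.sqrtm(Sbb).real)
    U0, s, V0t = scipy.linalg.svd(Wx @ Sxb @ Wb)
    U = Wx @ U0
    V = Wb @ V0t.T
    for j in range(U.shape[1]):
        U[:, j] /= np.sqrt(U[:, j] @ Sxx @ U[:, j])
    for j in range(V.shape[1]):
        V[:, j] /= np.sqrt(V[:, j] @ Sbb @ V[:, j])
    for j in range(min(U.shape[1], V.shape[1])):
        if U[:, j] @ Sxb @ V[:, j] < 0:
            V[:, j] = -V[:, j]
        if U[np.argmax(np.abs(U[:, j])), j] < 0:
            U[:, j] = -U[:, j]
            V[:, j] = -V[:, j]
    return s, U, V


def as_epochset(samples_by_channel: np.ndarray, fs: float = 250.0,
                n_epochs: int = 1, series_kind: str = "channels",
                labels=None) -> bf.EpochSet:
    """Wrap a channels x samples matrix into an EpochSet for fitting."""
    n_ch, n_total = samples_by_channel.shape
    n_t = n_total // n_epochs
    epochs = samples_by_channel[:, : n_epochs * n_t].reshape(
        n_ch, n_epochs, n_t).transpose(1, 0, 2)
    return bf.EpochSet(epochs=epochs, time_ms=np.arange(n_t) * 1000.0 / fs,
                       fs=fs, series_kind=series_kind, labels=labels)


def complementary_config(seed: int) -> bf.SimConfig:
    """Two-condition study with complementary class signals in both streams.

    The EEG carries a graded evoked-amplitude contrast at a fixed 180 ms lag
    (10 vs 11.5 µV bursts at snr 1), the blink carries an independent
    amplitude contrast (100 vs 110 µV pulses); with both signals moderately
    noisy, neither modality alone decodes at ceiling.
    """
    return bf.SimConfig(
        conditions=("stand", "walk"),
        evoked_lag={"stand": 180.0, "walk": 180.0},
        evoked_amplitude=10.0,
        evoked_amplitude_by_condition={"stand": 10.0, "walk": 11.5},
        snr=1.0,
        background_share=0.9,
        blink_amplitude_by_condition={"stand": 100.0, "walk": 110.0},
        seed=seed,
    )


def dominance_peaks(seed: int, n_epochs: int = 80,
                    step_samples: int = 8) -> dict[str, float]:
    """Peak post-blink accuracy of pcEEG+, pcEEG and syncBlink on one seed.

    Runs the full synchronization + fusion method on directly simulated
    epochs and returns each method's peak accuracy over windows centered in
    the 50–350 ms post-blink interval (where the generator places all class
    information).
    """
    cfg = complementary_config(seed)
    eeg, _ = bf.simulate_epochset(cfg, n_epochs_per_condition=n_epochs)
    blink, _ = bf.simulate_epochset(cfg, n_epochs_per_condition=n_epochs,
                                    series_kind="blink")
    offsets = []
    for cond in cfg.conditions:
        sel = eeg.select(np.flatnonzero(eeg.labels == cond))
        offsets.append(bf.compute_offset(bf.compute_gfp(sel)))
    offset = bf.average_offsets(offsets)
    blink_sync = bf.shift_blink(blink, offset)

    pcs = bf.fit_pca_select(eeg)
    fused = bf.fuse_concat(pcs, blink_sync)
    splits = bf.make_splits(eeg.labels, 5, 0.2, seed)

    peaks = {}
    for name, feats in [("pcEEG+", fused), ("pcEEG", pcs.as_epochset()),
                        ("syncBlink", blink_sync)]:
        curve = bf.decode_timecourse(feats, step_samples=step_samples,
                                     seed=seed, splits=splits, method=name)
        post = (curve.window_centers_ms >= 50.0) & (curve.window_centers_ms <= 350.0)
        peaks[name] = float(np.max(curve.acc[post]))
    return peaks
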