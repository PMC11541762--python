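"""Feature-level fusion of EEG with the aligned blink signal.

Two routes are implemented.  The concatenation route ("pcEEG+") reduces the
channel-space epochs to the smallest principal-component set capturing 95 %
of the variance and row-stacks the aligned blink trace onto it,

    Fusion_concat(t) = [PC_1(t), ..., PC_k(t), BC_sync(t)].

The canonical-correlation route solves, for covariance matrices S_xx, S_bb
and cross-covariance S_xb of the EEG and the aligned channel-space blink
signal, the eigenproblems

    S_xx^{-1} S_xb S_bb^{-1} S_xb^T u = λ² u          (and the v counterpart)

and fuses the per-trial canonical variates X'(t) = uᵀX(t), B'(t) = vᵀB(t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.decomposition import PCA

from .blink_extraction import EpochSet


@dataclass
class PrincipalComponentSet:
    """Retained PCs of a channel-space epoch set."""

    pc_epochs: np.ndarray                 # n_epochs x k x n_times
    loadings: np.ndarray                  # channels x k, orthonormal columns
    explained_variance_ratio: np.ndarray  # length k
    k: int
    channel_mean: np.ndarray              # per-channel mean removed before fit
    time_ms: np.ndarray
    fs: float
    labels: np.ndarray | None = None
    participant_id: str = "sub-01"

    def as_epochset(self) -> EpochSet:
        return EpochSet(
            epochs=self.pc_epochs, time_ms=self.time_ms, fs=self.fs,
            series_kind="components", labels=self.labels,
            series_names=tuple(f"PC{i + 1}" for i in range(self.k)),
            participant_id=self.participant_id,
        )


@dataclass
class CanonicalPair:
    """One canonical pair: weights, correlation, and per-trial variates."""

    u: np.ndarray            # EEG weights, uᵀ S_xx u = 1
    v: np.ndarray            # blink weights, vᵀ S_bb v = 1
    rho: float               # canonical correlation in [0, 1]
    S_xx: np.ndarray
    S_bb: np.ndarray
    S_xb: np.ndarray
    x_variate: np.ndarray    # n_epochs x n_times
    b_variate: np.ndarray    # n_epochs x n_times


@dataclass
class FusedEpochSet:
    """Stacked multimodal feature series per epoch."""

    fused_epochs: np.ndarray              # n_epochs x m x n_times
    provenance: str                       # "pcEEG+" | "CCA"
    #: row provenance as (start, stop[, step]) ranges into the series axis
    component_blocks: dict[str, tuple[int, ...]]
    time_ms: np.ndarray
    fs: float
    labels: np.ndarray | None = None
    participant_id: str = "sub-01"

    def as_epochset(self) -> EpochSet:
        return EpochSet(
            epochs=self.fused_epochs, time_ms=self.time_ms, fs=self.fs,
            series_kind="fused", labels=self.labels,
            participant_id=self.participant_id,
        )


# ---------------------------------------------------------------------------
# PCA route
# ---------------------------------------------------------------------------

def fit_pca_select(epochs: EpochSet, var_threshold: float = 0.95) -> PrincipalComponentSet:
    """PCA on channels x (epochs·times), keeping the smallest 95 %-variance set.

    Epochs are unfolded to one long multichannel record, per-channel means
    are removed, and the smallest k with cumulative explained variance ≥
    ``var_threshold`` is retained.  Component signs follow the convention
    that each loading's largest-magnitude entry is positive.
    """
    if epochs.series_kind != "channels":
        raise ValueError("PCA expects channel-space epochs")
    n_ep, n_ch, n_t = epochs.epochs.shape
    if n_ep * n_t <= n_ch:
        raise ValueError("need more samples (epochs x times) than channels")

    X = epochs.epochs.transpose(1, 0, 2).reshape(n_ch, n_ep * n_t)  # ch x samples
    if np.allclose(X.std(axis=1), 0):
        raise ValueError("zero-variance data")

    pca = PCA(n_components=None, svd_solver="full")
    pca.fit(X.T)
    evr = pca.explained_variance_ratio_
    k = int(np.searchsorted(np.cumsum(evr), var_threshold - 1e-12) + 1)
    k = min(k, evr.size)

    loadings = pca.components_[:k].T.copy()          # channels x k
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    loadings *= flip

    centered = epochs.epochs - pca.mean_[None, :, None]
    pc_epochs = np.einsum("ect,ck->ekt", centered, loadings)
    return PrincipalComponentSet(
        pc_epochs=pc_epochs, loadings=loadings,
        explained_variance_ratio=evr[:k].copy(), k=k,
        channel_mean=pca.mean_.copy(), time_ms=epochs.time_ms.copy(),
        fs=epochs.fs, labels=epochs.labels,
        participant_id=epochs.participant_id,
    )


def fuse_concat(pcs: PrincipalComponentSet, blink_sync: EpochSet) -> FusedEpochSet:
    """Row-stack the retained PCs with the aligned blink series (pcEEG+)."""
    if pcs.k < 1:
        raise ValueError("need at least one principal component")
    if blink_sync.n_epochs != pcs.pc_epochs.shape[0]:
        raise ValueError("epoch count mismatch between PCs and blink epochs")
    if blink_sync.n_times != pcs.pc_epochs.shape[2] or not np.allclose(
            blink_sync.time_ms, pcs.time_ms):
        raise ValueError("time grid mismatch between PCs and blink epochs")

    fused = np.concatenate([pcs.pc_epochs, blink_sync.epochs], axis=1)
    return FusedEpochSet(
        fused_epochs=fused, provenance="pcEEG+",
        component_blocks={"eeg": (0, pcs.k),
                          "blink": (pcs.k, pcs.k + blink_sync.n_series)},
        time_ms=pcs.time_ms.copy(), fs=pcs.fs, labels=pcs.labels,
        participant_id=pcs.participant_id,
    )


# ---------------------------------------------------------------------------
# CCA route
# ---------------------------------------------------------------------------

def fit_cca(
    eeg_epochs: EpochSet,
    blink_channelspace_sync: EpochSet,
    n_pairs: int = 1,
    ridge: float = 1e-8,
) -> list[CanonicalPair]:
    """Canonical correlation between EEG and aligned blink channel-space data.

    Covariances are pooled over all epochs and time points; a ridge term
    ``ridge * trace/dim`` stabilizes the inverses.  The eigenproblem is
    solved in its generalized symmetric form
    (S_xb S_bb⁻¹ S_xbᵀ) u = λ² S_xx u for numerical stability; pairs are
    returned sorted by descending canonical correlation with
    uᵀS_xx u = vᵀS_bb v = 1 and rho ≥ 0.
    """
    if eeg_epochs.n_epochs != blink_channelspace_sync.n_epochs or \
            eeg_epochs.n_times != blink_channelspace_sync.n_times:
        raise ValueError("EEG and blink epoch structures must match")
    n_pairs = int(n_pairs)
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")

    X = _unfold(eeg_epochs)     # ch_x x N, mean-removed
    B = _unfold(blink_channelspace_sync)
    N = X.shape[1]
    S_xx = X @ X.T / N
    S_bb = B @ B.T / N
    S_xb = X @ B.T / N
    S_xx = _ridge(S_xx, ridge)
    S_bb = _ridge(S_bb, ridge)

    try:
        Sbb_inv_SxbT = scipy.linalg.solve(S_bb, S_xb.T, assume_a="pos")
    except scipy.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular blink covariance; increase the ridge regularization term"
        ) from err
    A = S_xb @ Sbb_inv_SxbT            # S_xb S_bb^-1 S_xb^T, symmetric PSD
    A = (A + A.T) / 2.0
    try:
        lam2, U = scipy.linalg.eigh(A, (S_xx + S_xx.T) / 2.0)
    except scipy.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular EEG covariance; increase the ridge regularization term"
        ) from err

    order = np.argsort(lam2)[::-1]
    n_pairs = min(n_pairs, min(S_xx.shape[0], S_bb.shape[0]))
    pairs: list[CanonicalPair] = []
    mean_x = eeg_epochs.epochs.mean(axis=(0, 2))
    mean_b = blink_channelspace_sync.epochs.mean(axis=(0, 2))
    for j in order[:n_pairs]:
        u = U[:, j]
        u = u / np.sqrt(u @ S_xx @ u)          # eigh normalizes uᵀS_xx u = 1 already
        rho = float(np.sqrt(max(lam2[j], 0.0)))
        bv = Sbb_inv_SxbT @ u
        norm = np.sqrt(bv @ S_bb @ bv)
        v = bv / norm if norm > 0 else bv
        if u @ S_xb @ v < 0:
            v = -v
        i_max = int(np.argmax(np.abs(u)))
        if u[i_max] < 0:
            u, v = -u, -v
        x_var = np.einsum("c,ect->et", u, eeg_epochs.epochs - mean_x[None, :, None])
        b_var = np.einsum("c,ect->et", v,
                          blink_channelspace_sync.epochs - mean_b[None, :, None])
        pairs.append(CanonicalPair(
            u=u, v=v, rho=min(rho, 1.0), S_xx=S_xx, S_bb=S_bb, S_xb=S_xb,
            x_variate=x_var, b_variate=b_var,
        ))
    return pairs


def _unfold(epochs: EpochSet) -> np.ndarray:
    """series x (epochs·times) matrix with per-series means removed."""
    n_ep, n_s, n_t = epochs.epochs.shape
    X = epochs.epochs.transpose(1, 0, 2).reshape(n_s, n_ep * n_t)
    return X - X.mean(axis=1, keepdims=True)


def _ridge(S: np.ndarray, eps: float) -> np.ndarray:
    return S + eps * (np.trace(S) / S.shape[0]) * np.eye(S.shape[0])


def fuse_cca(pairs: list[CanonicalPair], template: EpochSet) -> FusedEpochSet:
    """Stack the canonical variates X' and B' of each pair as fused series.

    ``template`` supplies the time grid, labels, and bookkeeping (any of the
    epoch sets the pairs were fitted on).
    """
    if not pairs:
        raise ValueError("empty canonical pair list")
    series = []
    for p in pairs:
        series.append(p.x_variate)
        series.append(p.b_variate)
    fused = np.stack(series, axis=1)
    m = fused.shape[1]
    return FusedEpochSet(
        fused_epochs=fused, provenance="CCA",
        component_blocks={"eeg": (0, m, 2), "blink": (1, m, 2)},  # interleaved
        time_ms=template.time_ms.copy(), fs=template.fs,
        labels=template.labels, participant_id=template.participant_id,
    )
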