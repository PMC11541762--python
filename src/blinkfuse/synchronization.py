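"""Blink-to-GFP synchronization: offset estimation and blink alignment.

Global field power (GFP) is the spatial standard deviation across channels at
each time point of the epoch-averaged signal (Lehmann–Skrandies convention).
Its post-blink maximum marks the strongest blink-locked evoked response; the
latency difference between that maximum and the blink peak,

    Δt = t_GFP_max − t_blink_max,

is the synchronization offset.  The blink component trace is then shifted by
Δt, BC_sync(t) = BC(t + Δt), so that the ocular and neural streams peak in
register before fusion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .blink_extraction import EpochSet


@dataclass
class GFPProfile:
    """GFP time course of an epoch-averaged channel set (µV)."""

    gfp: np.ndarray
    time_ms: np.ndarray
    peak_time_ms: float
    peak_value: float
    search_window_ms: tuple[float, float]
    peak_on_boundary: bool
    fs: float
    condition: str = "pooled"
    participant_id: str = "sub-01"


@dataclass
class SyncOffset:
    """Estimated blink-peak → GFP-peak offset for one participant."""

    delta_t_ms: float
    delta_t_samples: int
    fs: float
    t_blink_max_ms: float = 0.0
    participant_id: str = "sub-01"
    condition: str = "pooled"
    truncated_peak: bool = False


def compute_gfp(
    epochs: EpochSet,
    search_window_ms: tuple[float, float] = (0.0, 500.0),
) -> GFPProfile:
    """Average epochs, then take the spatial SD across channels per time point.

    The peak is the argmax of the GFP within ``search_window_ms`` (default
    0–500 ms post-blink, where the blink-locked evoked response lives).  A
    peak landing on a search-window boundary is flagged as possibly
    truncated.
    """
    if epochs.series_kind not in ("channels", "components"):
        raise ValueError("GFP requires channel- or component-space epochs")
    if epochs.n_series < 2:
        raise ValueError("GFP is undefined for a single channel")
    if epochs.n_epochs < 1:
        raise ValueError("need at least one epoch")

    mean_map = epochs.epochs.mean(axis=0)           # series x times
    gfp = mean_map.std(axis=0)                      # population SD across channels

    lo, hi = search_window_ms
    in_win = np.flatnonzero((epochs.time_ms >= lo) & (epochs.time_ms <= hi))
    if in_win.size == 0:
        raise ValueError("search window contains no samples")
    peak_idx = in_win[int(np.argmax(gfp[in_win]))]
    on_boundary = peak_idx in (in_win[0], in_win[-1])

    return GFPProfile(
        gfp=gfp, time_ms=epochs.time_ms.copy(),
        peak_time_ms=float(epochs.time_ms[peak_idx]),
        peak_value=float(gfp[peak_idx]),
        search_window_ms=(float(lo), float(hi)),
        peak_on_boundary=bool(on_boundary),
        fs=epochs.fs, participant_id=epochs.participant_id,
    )


def blink_peak_latency(blink_epochs: EpochSet) -> float:
    """Latency (ms) of the mean blink trace maximum; ≈ 0 by epoch construction."""
    mean_trace = blink_epochs.epochs.mean(axis=0)[0]
    return float(blink_epochs.time_ms[int(np.argmax(mean_trace))])


def compute_offset(gfp: GFPProfile, blink_peak_ms: float = 0.0) -> SyncOffset:
    """Δt = t_GFP_max − t_blink_max, with the integer sample shift recorded."""
    delta_ms = gfp.peak_time_ms - blink_peak_ms
    return SyncOffset(
        delta_t_ms=float(delta_ms),
        delta_t_samples=int(round(delta_ms * gfp.fs / 1000.0)),
        fs=gfp.fs,
        t_blink_max_ms=float(blink_peak_ms),
        participant_id=gfp.participant_id,
        condition=gfp.condition,
        truncated_peak=gfp.peak_on_boundary,
    )


def average_offsets(offsets: list[SyncOffset]) -> SyncOffset:
    """Per-participant mean of condition offsets, re-quantized to samples.

    Averaging the per-condition shifts gives one standardized alignment per
    participant, so no condition is favored by its own alignment.
    """
    if not offsets:
        raise ValueError("empty offset list")
    pids = {o.participant_id for o in offsets}
    if len(pids) > 1:
        raise ValueError(f"offsets mix participants: {sorted(pids)}")
    fs = offsets[0].fs
    mean_ms = float(np.mean([o.delta_t_ms for o in offsets]))
    return SyncOffset(
        delta_t_ms=mean_ms,
        delta_t_samples=int(round(mean_ms * fs / 1000.0)),
        fs=fs,
        participant_id=offsets[0].participant_id,
        condition="pooled",
        truncated_peak=any(o.truncated_peak for o in offsets),
    )


def shift_blink(blink_epochs: EpochSet, offset: SyncOffset,
                fill: str = "edge") -> EpochSet:
    """Align the blink trace to the GFP peak: out(t) = in(t − Δt).

    With blink-peak-locked epochs (blink maximum at t = 0) and a positive
    offset Δt = t_GFP_max − t_blink_max, delaying every series by Δt moves
    the blink maximum onto the GFP maximum, so the cross-correlation lag
    between the mean aligned blink and the GFP is zero and one decoding
    window sees both modalities' peaks.  Vacated samples are filled by edge
    replication (default) or zeros; replication avoids step artifacts inside
    feature windows.  Applies unchanged to the channel-space back-projection
    BCS.
    """
    if blink_epochs.series_kind not in ("blink", "channels"):
        raise ValueError("shift_blink expects blink- or channel-space epochs")
    k = -offset.delta_t_samples
    n_t = blink_epochs.n_times
    if abs(k) >= n_t:
        raise ValueError(f"shift of {k} samples exceeds epoch length {n_t}")
    if fill not in ("edge", "zero"):
        raise ValueError("fill must be 'edge' or 'zero'")

    x = blink_epochs.epochs
    out = np.empty_like(x)
    if k == 0:
        out[:] = x
    elif k > 0:
        out[..., : n_t - k] = x[..., k:]
        out[..., n_t - k:] = x[..., -1:] if fill == "edge" else 0.0
    else:
        out[..., -k:] = x[..., :k]
        out[..., : -k] = x[..., :1] if fill == "edge" else 0.0
    return replace(blink_epochs, epochs=out)
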