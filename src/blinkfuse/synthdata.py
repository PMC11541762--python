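"""Synthetic mobile-EEG generator with an embedded blink source.

Emulates the kind of recording the pipeline targets: ~30 scalp channels at
250 Hz containing (i) a stereotyped frontal blink artifact, (ii) a
condition-dependent blink-locked evoked response whose global-field-power
peak lags the blink peak by a known per-condition offset, (iii) a few
broadband background sources, and (iv) additive 1/f or white sensor noise.
Every random draw is governed by a single seed and the full ground truth
(blink peak samples, per-blink condition, mixing matrix, true lags) is
returned, so each downstream stage can be tested against known answers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .blink_extraction import MONTAGE_30, EpochSet

#: per-condition lag (ms) between blink peak and evoked GFP peak; the three
#: default conditions mimic increasing locomotor complexity.
DEFAULT_LAGS = {"stand": 160.0, "walk": 200.0, "walk_obstacles": 240.0}


class ConfigurationError(ValueError):
    """A SimConfig field is inconsistent with the epoch window or physics."""


@dataclass
class SimConfig:
    """Parameters of the simulated recording.

    Amplitudes are in µV.  ``snr`` is the ratio of the evoked-burst peak
    amplitude to the per-channel noise SD; ``math.inf`` gives a noise-free
    recording.  ``blink_amplitude_by_condition`` adds a condition-dependent
    blink morphology (an independent, ocular class signal) on top of the
    condition-dependent evoked lag carried by the EEG.
    """

    n_channels: int = 30
    fs: float = 250.0
    duration: float = 240.0                      # seconds per condition
    conditions: tuple[str, ...] = ("stand", "walk", "walk_obstacles")
    blink_rate: float = 12.0                     # blinks / minute
    blink_amplitude: float = 100.0               # µV at the source
    blink_rise_ms: float = 100.0
    blink_fall_ms: float = 200.0
    blink_amplitude_by_condition: dict[str, float] | None = None
    evoked_lag: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LAGS))
    evoked_amplitude: float = 5.0                # µV burst peak at the source
    evoked_amplitude_by_condition: dict[str, float] | None = None
    evoked_freq_hz: float = 10.0
    evoked_duration_ms: float = 150.0
    evoked_topography: np.ndarray | None = None
    snr: float = 5.0
    noise_model: str = "pink"                    # "pink" | "white"
    n_background_sources: int = 3
    #: fraction of noise variance carried by shared background sources (the
    #: rest is channel-independent sensor noise); real EEG noise is spatially
    #: structured, which is what keeps the 95 %-variance PC set small
    background_share: float = 0.8
    epoch_window_ms: tuple[float, float] = (-500.0, 1000.0)
    min_blink_gap_s: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")
        if self.blink_rate <= 0:
            raise ConfigurationError("blink_rate must be positive")
        if not (self.snr > 0):
            raise ConfigurationError("snr must be positive (may be inf)")
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        if self.noise_model not in ("pink", "white"):
            raise ConfigurationError("noise_model must be 'pink' or 'white'")
        if not 0.0 <= self.background_share < 1.0:
            raise ConfigurationError("background_share must be in [0, 1)")
        if set(self.evoked_lag) != set(self.conditions):
            raise ConfigurationError("evoked_lag must name every condition")
        half = self.evoked_duration_ms / 2.0
        lo, hi = self.epoch_window_ms
        for cond, lag in self.evoked_lag.items():
            if not (lo <= lag - half and lag + half <= hi):
                raise ConfigurationError(
                    f"evoked lag {lag} ms for {cond!r} leaves the epoch window"
                )


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    blink_peak_samples: np.ndarray   # sorted sample indices
    condition_of_blink: np.ndarray   # label per blink
    mixing: np.ndarray               # channels x sources; source 0 is the blink
    delta_t_true: dict[str, float]   # ms per condition
    sources: np.ndarray | None = None  # sources x samples (continuous sims)

    def __post_init__(self) -> None:
        self.blink_peak_samples = np.asarray(self.blink_peak_samples, dtype=int)
        if self.blink_peak_samples.size and np.any(np.diff(self.blink_peak_samples) <= 0):
            raise ValueError("blink_peak_samples must be strictly increasing")
        if np.linalg.matrix_rank(self.mixing) < self.mixing.shape[1]:
            raise ValueError("mixing must have full column rank")


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def blink_pulse(fs: float, rise_ms: float, fall_ms: float) -> tuple[np.ndarray, int]:
    """Asymmetric unipolar pulse (half-cosine rise, slower half-cosine fall).

    Returns the unit-amplitude pulse and the index of its peak sample.
    """
    n_rise = max(2, int(round(rise_ms * fs / 1000.0)))
    n_fall = max(2, int(round(fall_ms * fs / 1000.0)))
    rise = 0.5 * (1 - np.cos(np.pi * np.arange(n_rise) / n_rise))
    fall = 0.5 * (1 + np.cos(np.pi * np.arange(1, n_fall + 1) / n_fall))
    return np.concatenate([rise, [1.0], fall]), n_rise


def evoked_burst(fs: float, freq_hz: float, duration_ms: float) -> tuple[np.ndarray, int]:
    """Hann-windowed cosine burst; the envelope maximum sits at the center."""
    n = int(round(duration_ms * fs / 1000.0))
    n += (n + 1) % 2  # odd length so the center is a sample
    t = (np.arange(n) - n // 2) / fs
    return np.hanning(n) * np.cos(2 * np.pi * freq_hz * t), n // 2


def make_noise(rng: np.random.Generator, shape: tuple[int, ...],
               model: str = "pink") -> np.ndarray:
    """Unit-SD Gaussian noise, optionally 1/f-shaped along the last axis."""
    x = rng.standard_normal(shape)
    if model == "white":
        return x
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0
    shaped = np.fft.irfft(np.fft.rfft(x, axis=-1) * scale, n=n, axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    return shaped / np.where(sd > 0, sd, 1.0)


def _topographies(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """channels x sources mixing matrix: blink, evoked, background."""
    n_ch = cfg.n_channels
    labels = MONTAGE_30 if n_ch == len(MONTAGE_30) else tuple(
        f"ch{i}" for i in range(n_ch))

    blink = np.zeros(n_ch)
    band_weight = {"Fp": 1.0, "F": 0.5, "FC": 0.25, "FT": 0.25, "C": 0.1}
    for i, lab in enumerate(labels):
        w = 0.02
        for prefix, val in sorted(band_weight.items(), key=lambda kv: -len(kv[0])):
            if lab.startswith(prefix):
                w = val
                break
        blink[i] = w
    if n_ch != len(MONTAGE_30):  # unnamed montage: front-loaded ramp
        blink = np.linspace(1.0, 0.02, n_ch)
    blink += 0.01 * rng.standard_normal(n_ch)  # break exact symmetry / rank ties
    blink = np.abs(blink)

    if cfg.evoked_topography is not None:
        evoked = np.asarray(cfg.evoked_topography, dtype=float)
        if evoked.shape != (n_ch,):
            raise ConfigurationError("evoked_topography must have n_channels entries")
    else:
        evoked = np.zeros(n_ch)
        central = {"C", "CP", "P", "Cz", "Pz"}
        for i, lab in enumerate(labels):
            evoked[i] = 1.0 if any(lab.startswith(p) for p in ("C", "CP", "P")) else 0.1
        if n_ch != len(MONTAGE_30):
            evoked = np.linspace(0.1, 1.0, n_ch)
        evoked += 0.05 * rng.standard_normal(n_ch)
    evoked = evoked / np.abs(evoked).max()

    bg = rng.standard_normal((n_ch, cfg.n_background_sources)) * 0.3
    mixing = np.column_stack([blink, evoked, bg])
    return mixing


def _noise_scales(cfg: SimConfig, mixing: np.ndarray) -> tuple[float, float]:
    """Split the snr-governed noise budget into background and sensor parts.

    The per-channel noise SD is evoked_amplitude / snr; a fraction
    ``background_share`` of its variance is carried by the shared background
    sources (scaled through their mixing columns), the rest by independent
    sensor noise.  Returns (background source SD, sensor noise SD).
    """
    if not math.isfinite(cfg.snr):
        return 0.0, 0.0
    noise_sd = cfg.evoked_amplitude / cfg.snr
    bg_cols = mixing[:, 2:]
    if bg_cols.size == 0 or cfg.background_share == 0.0:
        return 0.0, noise_sd
    mean_gain = float(np.sqrt(np.mean(np.sum(bg_cols ** 2, axis=1))))
    bg_src_sd = noise_sd * math.sqrt(cfg.background_share) / max(mean_gain, 1e-12)
    sensor_sd = noise_sd * math.sqrt(1.0 - cfg.background_share)
    return bg_src_sd, sensor_sd


def _blink_times(cfg: SimConfig, rng: np.random.Generator,
                 n_samples: int) -> np.ndarray:
    """Renewal process: minimum gap plus an exponential tail.

    The gap distribution is ``min_gap + Exp(mean_gap - min_gap)`` so the mean
    inter-blink interval equals 60/blink_rate and the realized count stays
    Poisson-consistent while keeping epochs separable.
    """
    mean_gap = 60.0 / cfg.blink_rate
    tail = max(mean_gap - cfg.min_blink_gap_s, 1e-3)
    margin = int(round(2.0 * cfg.fs))  # keep the epoch window in bounds
    t = margin + int(round(rng.exponential(tail) * cfg.fs))
    peaks = []
    while t < n_samples - margin:
        peaks.append(t)
        gap = cfg.min_blink_gap_s + rng.exponential(tail)
        t += int(round(gap * cfg.fs))
    return np.asarray(peaks, dtype=int)


# ---------------------------------------------------------------------------
# continuous simulation
# ---------------------------------------------------------------------------

def simulate_recording(config: SimConfig):
    """Simulate a continuous recording; returns (ContinuousRecording, GroundTruth).

    Conditions are interleaved in 30 s blocks; every blink in a block carries
    that block's condition label, and its evoked burst is centered at the
    blink peak plus the condition's true lag.
    """
    from .blink_extraction import ContinuousRecording

    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n_cond = len(config.conditions)
    block_s = min(30.0, config.duration)
    n_blocks_per_cond = max(1, int(round(config.duration / block_s)))
    block_n = int(round(block_s * fs))
    total_n = block_n * n_blocks_per_cond * n_cond

    mixing = _topographies(config, rng)
    n_src = mixing.shape[1]
    sources = np.zeros((n_src, total_n))

    # background sources: shared band-limited noise, always on; their level
    # and the sensor noise split the snr-governed noise budget
    bg_src_sd, sensor_sd = _noise_scales(config, mixing)
    for s in range(2, n_src):
        sources[s] = make_noise(rng, (total_n,), config.noise_model) * bg_src_sd

    pulse, pulse_peak = blink_pulse(fs, config.blink_rise_ms, config.blink_fall_ms)
    burst, burst_center = evoked_burst(fs, config.evoked_freq_hz, config.evoked_duration_ms)

    # interleaved condition blocks
    block_cond = [config.conditions[(b % n_cond)] for b in range(n_blocks_per_cond * n_cond)]

    all_peaks: list[int] = []
    all_conds: list[str] = []
    for b, cond in enumerate(block_cond):
        start = b * block_n
        peaks = _blink_times(config, rng, block_n) + start
        amp = config.blink_amplitude
        if config.blink_amplitude_by_condition:
            amp = config.blink_amplitude_by_condition.get(cond, amp)
        ev_amp = config.evoked_amplitude
        if config.evoked_amplitude_by_condition:
            ev_amp = config.evoked_amplitude_by_condition.get(cond, ev_amp)
        lag_n = int(round(config.evoked_lag[cond] * fs / 1000.0))
        for p in peaks:
            _add(sources[0], pulse, p - pulse_peak, amp)
            _add(sources[1], burst, p + lag_n - burst_center, ev_amp)
        all_peaks.extend(int(p) for p in peaks)
        all_conds.extend([cond] * len(peaks))

    data = mixing @ sources
    if sensor_sd > 0:
        data = data + sensor_sd * make_noise(rng, data.shape, config.noise_model)

    order = np.argsort(all_peaks)
    truth = GroundTruth(
        blink_peak_samples=np.asarray(all_peaks, dtype=int)[order],
        condition_of_blink=np.asarray(all_conds, dtype=object)[order],
        mixing=mixing,
        delta_t_true=dict(config.evoked_lag),
        sources=sources,
    )
    labels = MONTAGE_30 if config.n_channels == len(MONTAGE_30) else tuple(
        f"ch{i}" for i in range(config.n_channels))
    rec = ContinuousRecording(data=data, fs=fs, channel_labels=labels,
                              participant_id=f"sim-{config.seed:04d}")
    return rec, truth


def _add(target: np.ndarray, waveform: np.ndarray, start: int, scale: float) -> None:
    """Add ``scale * waveform`` into ``target`` starting at ``start``, clipped."""
    lo = max(start, 0)
    hi = min(start + waveform.size, target.size)
    if hi <= lo:
        return
    target[lo:hi] += scale * waveform[lo - start: hi - start]


# ---------------------------------------------------------------------------
# direct epoch simulation (bypasses detection)
# ---------------------------------------------------------------------------

def simulate_epochset(
    config: SimConfig,
    n_epochs_per_condition: int = 100,
    series_kind: str = "channels",
    include_blink_artifact: bool = False,
):
    """Directly emit blink-locked epochs; returns (EpochSet, GroundTruth).

    ``series_kind='channels'`` gives scalp epochs carrying the evoked burst
    at each condition's true lag (the blink artifact is omitted unless
    ``include_blink_artifact``, mirroring component-cleaned EEG);
    ``series_kind='blink'`` gives the matching single-series blink-component
    epochs with the pulse peak at time 0.  The two views are trial-aligned:
    the same seed produces the same trial order and noise stream structure.
    """
    config.validate()
    if n_epochs_per_condition <= 0:
        raise ConfigurationError("n_epochs_per_condition must be positive")
    if series_kind not in ("channels", "blink"):
        raise ValueError("series_kind must be 'channels' or 'blink'")

    rng = np.random.default_rng(config.seed)
    fs = config.fs
    lo = int(round(config.epoch_window_ms[0] * fs / 1000.0))
    hi = int(round(config.epoch_window_ms[1] * fs / 1000.0))
    n_t = hi - lo + 1
    time_ms = np.arange(lo, hi + 1) / fs * 1000.0
    zero = -lo  # index of the blink peak on the grid

    mixing = _topographies(config, rng)
    pulse, pulse_peak = blink_pulse(fs, config.blink_rise_ms, config.blink_fall_ms)
    burst, burst_center = evoked_burst(fs, config.evoked_freq_hz, config.evoked_duration_ms)

    labels = np.repeat(np.asarray(config.conditions, dtype=object),
                       n_epochs_per_condition)
    order = rng.permutation(labels.size)  # interleave conditions
    labels = labels[order]

    n_ep = labels.size
    eeg = np.zeros((n_ep, config.n_channels, n_t))
    blink = np.zeros((n_ep, 1, n_t))
    noise_sd = 0.0 if not math.isfinite(config.snr) else config.evoked_amplitude / config.snr
    bg_src_sd, sensor_sd = _noise_scales(config, mixing)
    n_bg = config.n_background_sources

    for e, cond in enumerate(labels):
        lag_n = int(round(config.evoked_lag[cond] * fs / 1000.0))
        ev_amp = config.evoked_amplitude
        if config.evoked_amplitude_by_condition:
            ev_amp = config.evoked_amplitude_by_condition.get(cond, ev_amp)
        ev = np.zeros(n_t)
        _add(ev, burst, zero + lag_n - burst_center, ev_amp)
        eeg[e] = mixing[:, 1:2] * ev[None, :]
        amp = config.blink_amplitude
        if config.blink_amplitude_by_condition:
            amp = config.blink_amplitude_by_condition.get(cond, amp)
        bl = np.zeros(n_t)
        _add(bl, pulse, zero - pulse_peak, amp)
        blink[e, 0] = bl
        if include_blink_artifact:
            eeg[e] += mixing[:, 0:1] * bl[None, :]
        if bg_src_sd > 0 and n_bg > 0:
            bg = bg_src_sd * make_noise(rng, (n_bg, n_t), config.noise_model)
            eeg[e] += mixing[:, 2:] @ bg
        if sensor_sd > 0:
            eeg[e] += sensor_sd * make_noise(rng, (config.n_channels, n_t), config.noise_model)
        if noise_sd > 0:
            blink[e, 0] += noise_sd * make_noise(rng, (n_t,), config.noise_model)

    truth = GroundTruth(
        blink_peak_samples=np.arange(n_ep, dtype=int) * n_t + zero,
        condition_of_blink=labels.copy(),
        mixing=mixing,
        delta_t_true=dict(config.evoked_lag),
    )
    pid = f"sim-{config.seed:04d}"
    if series_kind == "channels":
        ch_names = MONTAGE_30 if config.n_channels == len(MONTAGE_30) else tuple(
            f"ch{i}" for i in range(config.n_channels))
        out = EpochSet(epochs=eeg, time_ms=time_ms, fs=fs, series_kind="channels",
                       labels=labels, series_names=ch_names, participant_id=pid)
    else:
        out = EpochSet(epochs=blink, time_ms=time_ms, fs=fs, series_kind="blink",
                       labels=labels, series_names=("BC",), participant_id=pid)
    return out, truth
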