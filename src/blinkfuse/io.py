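"""Readers and writers: continuous EEG, HDF5 epoch containers, CSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .blink_extraction import ContinuousRecording, EpochSet
from .synthdata import GroundTruth


def read_continuous(path: str | Path, participant_id: str | None = None) -> ContinuousRecording:
    """Read EDF, BrainVision (.vhdr) or FIF continuous EEG via mne (µV out)."""
    import mne

    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose=False)
    elif suffix == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose=False)
    elif suffix == ".fif":
        raw = mne.io.read_raw_fif(path, preload=True, verbose=False)
    else:
        raise ValueError(f"unsupported continuous format: {suffix}")
    data = raw.get_data() * 1e6  # volts -> µV
    return ContinuousRecording(
        data=data, fs=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        participant_id=participant_id or path.stem,
    )


def write_continuous_fif(rec: ContinuousRecording, path: str | Path) -> None:
    """Export a continuous recording to FIF (mne's native format)."""
    import mne

    info = mne.create_info(list(rec.channel_labels), rec.fs, ch_types="eeg")
    raw = mne.io.RawArray(rec.data * 1e-6, info, verbose=False)  # µV -> volts
    raw.save(str(path), overwrite=True, verbose=False)


def write_epochs_h5(path: str | Path, epochs: EpochSet,
                    truth: GroundTruth | None = None) -> None:
    """HDF5 epoch container: epochs, time_ms, labels (+ ground truth)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=epochs.epochs)
        f.create_dataset("time_ms", data=epochs.time_ms)
        if epochs.labels is not None:
            f.create_dataset("labels",
                             data=np.asarray(epochs.labels, dtype="S"))
        f.attrs["fs"] = epochs.fs
        f.attrs["series_kind"] = epochs.series_kind
        f.attrs["participant_id"] = epochs.participant_id
        if truth is not None:
            f.create_dataset("blink_samples", data=truth.blink_peak_samples)
            f.create_dataset("mixing", data=truth.mixing)
            f.create_dataset(
                "condition_of_blink",
                data=np.asarray(truth.condition_of_blink, dtype="S"))
            f.attrs["delta_t_true"] = json.dumps(truth.delta_t_true)


def read_epochs_h5(path: str | Path) -> tuple[EpochSet, GroundTruth | None]:
    with h5py.File(path, "r") as f:
        labels = None
        if "labels" in f:
            labels = np.asarray([s.decode() for s in f["labels"][()]], dtype=object)
        epochs = EpochSet(
            epochs=f["epochs"][()], time_ms=f["time_ms"][()],
            fs=float(f.attrs["fs"]), series_kind=str(f.attrs["series_kind"]),
            labels=labels, participant_id=str(f.attrs.get("participant_id", "sub-01")),
        )
        truth = None
        if "blink_samples" in f:
            truth = GroundTruth(
                blink_peak_samples=f["blink_samples"][()],
                condition_of_blink=np.asarray(
                    [s.decode() for s in f["condition_of_blink"][()]], dtype=object),
                mixing=f["mixing"][()],
                delta_t_true=json.loads(f.attrs["delta_t_true"]),
            )
    return epochs, truth


def read_unmixing(path: str | Path, delimiter: str | None = None) -> np.ndarray:
    """Delimited-text unmixing matrix (components x channels)."""
    return np.loadtxt(path, delimiter=delimiter, ndmin=2)


def read_events_csv(path: str | Path) -> pd.DataFrame:
    """Event table with columns ``sample`` and ``label``."""
    df = pd.read_csv(path)
    missing = {"sample", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    return df


def offsets_to_csv(offsets, path: str | Path) -> None:
    pd.DataFrame([
        {"participant": o.participant_id, "condition": o.condition,
         "delta_t_ms": o.delta_t_ms, "delta_t_samples": o.delta_t_samples,
         "truncated_peak": o.truncated_peak}
        for o in offsets
    ]).to_csv(path, index=False)


def curve_to_csv(curve, path: str | Path) -> None:
    pd.DataFrame({
        "participant": curve.participant_id, "method": curve.method,
        "window_center_ms": curve.window_centers_ms,
        "acc": curve.acc, "sen": curve.sen, "spe": curve.spe,
    }).to_csv(path, index=False)


def tgm_to_csv(tgm, path: str | Path) -> None:
    n_tr, n_te = tgm.scores.shape
    tr, te = np.meshgrid(tgm.train_centers_ms, tgm.test_centers_ms, indexing="ij")
    pd.DataFrame({
        "train_ms": tr.ravel(), "test_ms": te.ravel(),
        "score": tgm.scores.ravel(),
    }).to_csv(path, index=False)
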