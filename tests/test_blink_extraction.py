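"""Preprocessing, blink-component selection, detection, epoching, rejection."""

import numpy as np
import pytest

import blinkfuse as bf
from blinkfuse.blink_extraction import (
    ContinuousRecording,
    EmptyEpochSetError,
    NoBlinkComponentError,
    UnrecoverableRecordingError,
    preprocess,
)
from blinkfuse.synthdata import blink_pulse


def _rec(data, fs=250.0):
    labels = tuple(f"ch{i}" for i in range(data.shape[0]))
    return ContinuousRecording(data=data, fs=fs, channel_labels=labels)


# ---------------------------------------------------------------------------
# preprocess
# ---------------------------------------------------------------------------

class TestPreprocess:
    def test_line_noise_attenuated_over_20_db(self):
        fs = 500.0
        t = np.arange(int(80 * fs)) / fs
        rng = np.random.default_rng(0)
        amps = [50.0, 30.0, 20.0, 10.0]
        data = np.vstack([a * np.sin(2 * np.pi * 50.0 * t) for a in amps])
        data += 0.5 * rng.standard_normal(data.shape)
        out = preprocess(_rec(data, fs), correlation_threshold=-1.0)
        interior = slice(5000, -5000)
        freqs = np.fft.rfftfreq(out.data[:, interior].shape[1], d=1 / out.fs)
        bin50 = int(np.argmin(np.abs(freqs - 50.0)))
        power_out = np.abs(np.fft.rfft(out.data[:, interior], axis=1))[:, bin50]
        power_in = np.abs(np.fft.rfft(data[:, ::2][:, interior], axis=1))[:, bin50]
        att_db = 20 * np.log10(power_out.sum() / power_in.sum())
        assert att_db < -20.0

    def test_downsample_sample_count(self):
        n = 10001
        rng = np.random.default_rng(1)
        data = rng.standard_normal((3, n))
        out = preprocess(_rec(data, 500.0), target_fs=250.0,
                         correlation_threshold=-1.0)
        assert out.data.shape[1] == -(-n // 2)  # ceil(n/2)
        assert out.fs == 250.0

    def test_constant_channel_flagged_as_flatline(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((4, 5000)) * 10
        data[2] = 100.0  # DC-offset channel, constant throughout
        out = preprocess(_rec(data), correlation_threshold=-1.0)
        assert "ch2" in out.bad_channels

    def test_all_channels_flagged_is_unrecoverable(self):
        data = np.full((3, 5000), 7.0)
        with pytest.raises(UnrecoverableRecordingError):
            preprocess(_rec(data))

    def test_cutoff_above_nyquist_rejected(self):
        data = np.random.default_rng(0).standard_normal((2, 1000))
        with pytest.raises(ValueError):
            preprocess(_rec(data, fs=250.0), lowpass_hz=200.0)


# ---------------------------------------------------------------------------
# identify_blink_component
# ---------------------------------------------------------------------------

def _decomp(mixing, acts, flags):
    unmixing = np.linalg.pinv(mixing)
    return bf.ComponentDecomposition(unmixing=unmixing, mixing=mixing,
                                     activations=acts,
                                     eye_candidate_flags=flags)


class TestIdentifyBlinkComponent:
    def test_single_positive_candidate(self):
        rng = np.random.default_rng(3)
        mixing = np.array([[1.0, 0.2], [0.9, 0.1], [0.1, 1.0], [0.0, 0.9]])
        acts = rng.standard_normal((2, 500))
        idx = bf.identify_blink_component(
            _decomp(mixing, acts, np.array([True, False])), 0, 1)
        assert idx == 0

    def test_blink_beats_saccade(self):
        # blink-like: same-sign anterior weights (L/R projections correlate
        # positively); saccade-like: opposite signs (negative correlation)
        rng = np.random.default_rng(4)
        mixing = np.array([[1.0, 1.0], [0.9, -0.8], [0.1, 0.1], [0.1, 0.0]])
        acts = rng.standard_normal((2, 500))
        d = _decomp(mixing, acts, np.array([True, True]))
        left = mixing[0, :, None] * acts
        right = mixing[1, :, None] * acts
        rs = [np.corrcoef(left[c], right[c])[0, 1] for c in range(2)]
        assert rs[0] > 0 > rs[1]
        assert bf.identify_blink_component(d, 0, 1) == 0

    def test_all_negative_correlations_error(self):
        rng = np.random.default_rng(5)
        mixing = np.array([[1.0, 0.8], [-0.9, -0.7], [0.1, 0.2], [0.0, 0.1]])
        acts = rng.standard_normal((2, 500))
        with pytest.raises(NoBlinkComponentError):
            bf.identify_blink_component(
                _decomp(mixing, acts, np.array([True, True])), 0, 1)

    def test_no_candidates_error(self):
        rng = np.random.default_rng(6)
        mixing = np.array([[1.0], [0.9], [0.1], [0.0]])
        with pytest.raises(NoBlinkComponentError):
            bf.identify_blink_component(
                _decomp(mixing, rng.standard_normal((1, 100)),
                        np.array([False])), 0, 1)

    def test_recovers_ground_truth_source_on_simulation(self):
        cfg = bf.SimConfig(duration=60.0, snr=5.0, seed=8)
        rec, truth = bf.simulate_recording(cfg)
        from blinkfuse.pipeline import decomposition_from_truth
        decomp = decomposition_from_truth(rec, truth)
        decomp.eye_candidate_flags[:] = True  # make every component a candidate
        assert bf.identify_blink_component(decomp, 0, 1) == 0


# ---------------------------------------------------------------------------
# detect_blinks
# ---------------------------------------------------------------------------

class TestDetectBlinks:
    def test_constant_signal_gives_no_events(self):
        events = bf.detect_blinks(np.full(1000, 3.0), fs=250.0)
        assert len(events) == 0

    def test_two_pulses_found_at_their_maxima(self):
        fs = 250.0
        rng = np.random.default_rng(7)
        x = rng.standard_normal(5000)
        pulse, peak = blink_pulse(fs, 100.0, 200.0)
        for start in (1000, 3000):
            x[start:start + pulse.size] += 10.0 * pulse
        events = bf.detect_blinks(x, fs=fs)

        # independent brute-force oracle: scan contiguous supra-threshold
        # runs of the constructed series by hand
        thr = x.mean() + 1.5 * x.std()
        above = x > thr
        runs, start = [], None
        for i, a in enumerate(above):
            if a and start is None:
                start = i
            elif not a and start is not None:
                runs.append((start, i))
                start = None
        expected = [s + int(np.argmax(x[s:e])) for s, e in runs
                    if e - s >= int(round(0.050 * fs))]
        assert list(events.peak_samples) == expected
        assert len(events) == 2
        for start in (1000, 3000):
            # event lands exactly on the maximum of the noisy pulse
            region = x[start:start + pulse.size]
            target = start + int(np.argmax(region))
            assert np.min(np.abs(events.peak_samples - target)) == 0

    def test_peaks_below_threshold_ignored(self):
        # a sinusoid never exceeds mean + 1.5 SD (max/SD = sqrt(2) < 1.5)
        fs = 250.0
        x = np.sin(2 * np.pi * 2.0 * np.arange(2500) / fs)
        assert x.max() < x.mean() + 1.5 * x.std()
        assert len(bf.detect_blinks(x, fs=fs)) == 0

    def test_recall_and_precision_on_simulation(self):
        cfg = bf.SimConfig(conditions=("stand",), evoked_lag={"stand": 160.0},
                           duration=300.0, snr=5.0, seed=10)
        rec, truth = bf.simulate_recording(cfg)
        acts = np.linalg.pinv(truth.mixing) @ rec.data
        events = bf.detect_blinks(acts[0], fs=rec.fs)
        tol = int(round(0.020 * rec.fs))
        true_peaks = truth.blink_peak_samples
        hits = sum(np.min(np.abs(true_peaks - p)) <= tol
                   for p in events.peak_samples)
        recall = hits / true_peaks.size
        precision = hits / max(len(events), 1)
        assert recall >= 0.95 and precision >= 0.95


# ---------------------------------------------------------------------------
# epoch_blink_locked
# ---------------------------------------------------------------------------

class TestEpoching:
    def test_inclusive_window_span(self):
        fs = 250.0
        data = np.arange(1400, dtype=float)[None, :]
        ep = bf.epoch_blink_locked(data, fs, np.array([1000]))
        assert ep.n_times == 376  # 1500 ms / 4 ms + 1, inclusive endpoints
        np.testing.assert_array_equal(ep.epochs[0, 0], np.arange(875, 1251))
        assert ep.time_ms[0] == -500.0 and ep.time_ms[-1] == 1000.0
        assert 0.0 in ep.time_ms

    def test_window_underrun_drops_event(self):
        data = np.zeros((2, 1000))
        labels = np.array(["a", "b"], dtype=object)
        ep = bf.epoch_blink_locked(data, 250.0, np.array([10, 500]),
                                   labels=labels)
        assert ep.n_epochs == 1
        np.testing.assert_array_equal(ep.labels, ["b"])

    def test_three_events_three_epochs(self):
        data = np.zeros((2, 3000))
        ep = bf.epoch_blink_locked(data, 250.0, np.array([500, 1200, 2000]))
        assert ep.n_epochs == 3

    def test_no_retained_events_errors(self):
        with pytest.raises(EmptyEpochSetError):
            bf.epoch_blink_locked(np.zeros((2, 300)), 250.0, np.array([10]))


# ---------------------------------------------------------------------------
# reject_epochs
# ---------------------------------------------------------------------------

def _clean_epochs(n, seed=0, sd=10.0):
    rng = np.random.default_rng(seed)
    epochs = rng.standard_normal((n, 4, 100)) * sd
    labels = np.asarray([f"c{i % 2}" for i in range(n)], dtype=object)
    return bf.EpochSet(epochs=epochs, time_ms=np.arange(100) * 4.0, fs=250.0,
                       labels=labels)


class TestRejectEpochs:
    def test_clean_epochs_untouched(self):
        ep = _clean_epochs(20)
        out, log = bf.reject_epochs(ep)
        assert log.n_rejected == 0
        np.testing.assert_array_equal(out.epochs, ep.epochs)

    def test_single_absolute_violator_removed(self):
        ep = _clean_epochs(21, seed=1)
        ep.epochs[7, 2, 50] = 600.0
        out, log = bf.reject_epochs(ep)
        assert log.iterations == [[7]]
        assert out.n_epochs == 20
        assert np.abs(out.epochs).max() < 500.0

    def test_iteration_cap_schedule(self):
        # 100 epochs, 30 absolute violators: removals per iteration are
        # capped at floor(0.10 * current_n) -> 10, 9, 8, then the last 3
        ep = _clean_epochs(100, seed=2)
        violators = np.arange(30)
        for i in violators:
            ep.epochs[i, 0, 10] = 600.0 + i
        out, log = bf.reject_epochs(ep)
        assert [len(it) for it in log.iterations] == [10, 9, 8, 3]
        assert sorted(i for it in log.iterations for i in it) == list(range(30))
        assert out.n_epochs == 70

    def test_idempotent_after_convergence(self):
        ep = _clean_epochs(50, seed=3)
        ep.epochs[5, 1, 20] = 700.0
        once, _ = bf.reject_epochs(ep)
        twice, log2 = bf.reject_epochs(once)
        assert log2.n_rejected == 0
        np.testing.assert_array_equal(once.epochs, twice.epochs)

    def test_labels_follow_retained_epochs(self):
        ep = _clean_epochs(30, seed=4)
        ep.epochs[4, 0, 0] = 900.0
        ep.epochs[9, 0, 0] = 900.0
        out, log = bf.reject_epochs(ep)
        removed = {i for it in log.iterations for i in it}
        assert removed == {4, 9}
        kept = [i for i in range(30) if i not in removed]
        np.testing.assert_array_equal(out.labels, ep.labels[kept])

    def test_all_epochs_rejected_errors(self):
        ep = _clean_epochs(3, seed=5)
        ep.epochs[:, 0, 0] = 1000.0
        with pytest.raises(EmptyEpochSetError):
            bf.reject_epochs(ep)
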