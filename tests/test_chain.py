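"""Preprocessing chain: crop, rejection, CAR, epoching, baseline, normalization,
and batch/streaming agreement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from mibci.containers import Marker, RawRecording
from mibci.preprocess.chain import (ChannelRejectRules, OfflinePreprocessor,
                                    PreprocessConfig, StreamingPreprocessor,
                                    apply_normalization, baseline_correct,
                                    common_average_reference, crop_head, epoch,
                                    normalize_sessions, preprocess_recordings,
                                    reject_channels)
from mibci.synthdata import (ParadigmSpec, SimConfig, TASK_MARKER_PREFIX,
                             generate_calibration, generate_recording)

FS = 250.0


def flat_recording(n_ch=4, seconds=70.0, markers=()):
    rng = np.random.default_rng(0)
    return RawRecording(
        data=rng.standard_normal((n_ch, int(seconds * FS))), fs=FS,
        channel_names=[f"ch{i}" for i in range(n_ch)], markers=list(markers))


class TestCrop:
    def test_duration_and_marker_shift(self):
        rec = flat_recording(markers=[Marker(9.5, "early"), Marker(12.0, "late")])
        out = crop_head(rec, 10.0)
        assert out.duration == pytest.approx(60.0)
        assert [m.label for m in out.markers] == ["late"]
        assert out.markers[0].onset == pytest.approx(2.0)

    def test_too_short(self):
        with pytest.raises(ValueError):
            crop_head(flat_recording(seconds=5.0), 10.0)


class TestChannelRejection:
    def test_flatline_rejected(self):
        rec = flat_recording()
        rec.data[1] = 0.0
        kept, rejected = reject_channels(rec)
        assert rejected == ["ch1"]
        assert kept.channel_names == ["ch0", "ch2", "ch3"]

    def test_noisy_channel_rejected(self):
        rec = flat_recording(n_ch=8)
        rec.data[2] *= 20.0
        _, rejected = reject_channels(rec)
        assert rejected == ["ch2"]

    def test_spike_rejected(self):
        rec = flat_recording()
        rec.data[0, 100] = 600.0
        _, rejected = reject_channels(rec)
        assert "ch0" in rejected

    def test_clean_recording_untouched(self):
        kept, rejected = reject_channels(flat_recording())
        assert rejected == []
        assert kept.n_channels == 4

    def test_all_rejected_errors(self):
        rec = flat_recording(n_ch=2)
        rec.data[:] = 0.0
        with pytest.raises(ValueError, match="unusable"):
            reject_channels(rec)

    def test_bad_rules(self):
        with pytest.raises(ValueError):
            ChannelRejectRules(flatline_sd_floor=0.0)


class TestCAR:
    def test_worked_example(self):
        out = common_average_reference(np.array([[1.0, 3.0], [2.0, 4.0]]))
        assert np.allclose(out, [[-0.5, -0.5], [0.5, 0.5]])

    def test_idempotent(self, rng):
        x = common_average_reference(rng.standard_normal((5, 100)))
        assert np.allclose(common_average_reference(x), x)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(arrays(float, (4, 16), elements=st.floats(-100, 100)))
    def test_zero_cross_channel_mean(self, x):
        out = common_average_reference(x)
        assert np.all(np.abs(out.mean(axis=0)) < 1e-12)

    def test_single_channel_errors(self):
        with pytest.raises(ValueError):
            common_average_reference(np.zeros((1, 10)))


class TestEpoching:
    def _rec_with_tasks(self, onsets, seconds=60.0, label="arrow_left"):
        markers = []
        for t in onsets:
            markers.append(Marker(t - 1.0, label))
            markers.append(Marker(t, TASK_MARKER_PREFIX + label))
        return flat_recording(seconds=seconds, markers=markers)

    def test_epoch_shapes(self):
        rec = self._rec_with_tasks([10.0, 20.0, 30.0])
        eps = epoch(rec, {"arrow_left": "left_mi"})
        assert eps.epochs.shape == (3, 4, 750)
        assert list(eps.labels) == ["left_mi"] * 3

    def test_trailing_marker_dropped(self):
        rec = self._rec_with_tasks([10.0, 59.5])
        eps = epoch(rec, {"arrow_left": "left_mi"})
        assert eps.n_trials == 1
        assert eps.dropped == 1

    def test_unmapped_label_warned(self):
        rec = self._rec_with_tasks([10.0, 20.0])
        rec.markers.append(Marker(30.0, TASK_MARKER_PREFIX + "mystery"))
        with pytest.warns(UserWarning, match="unmapped"):
            eps = epoch(rec, {"arrow_left": "left_mi"})
        assert eps.n_trials == 2

    def test_bookkeeping_epochs_plus_dropped(self):
        onsets = [5.0, 10.0, 20.0, 58.5]
        rec = self._rec_with_tasks(onsets)
        eps = epoch(rec, {"arrow_left": "left_mi"})
        assert eps.n_trials + eps.dropped == len(onsets)

    def test_no_markers_errors(self):
        with pytest.raises(ValueError):
            epoch(flat_recording(), {"arrow_left": "left_mi"})


class TestBaseline:
    def _eps(self, offset=7.0):
        rec = flat_recording(seconds=40.0)
        rec.data += offset
        markers = []
        for t in (10.0, 20.0):
            markers.append(Marker(t, TASK_MARKER_PREFIX + "arrow_left"))
        rec = rec.copy_with(markers=markers)
        return epoch(rec, {"arrow_left": "left_mi"})

    def test_constant_offset_removed(self):
        eps = baseline_correct(self._eps(offset=7.0))
        assert abs(eps.epochs.mean()) < 0.3  # offset of 7 µV gone, noise remains

    def test_ramp_oracle(self):
        fs = FS
        n = int(40 * fs)
        ramp = np.arange(n) / fs  # 1 unit per second
        rec = RawRecording(data=np.tile(ramp, (2, 1)), fs=fs,
                           channel_names=["a", "b"],
                           markers=[Marker(10.0, TASK_MARKER_PREFIX + "x")])
        eps = epoch(rec, {"x": "left_mi"})
        out = baseline_correct(eps, baseline=(-1.0, 0.0), cue_duration=1.0)
        # baseline covers t in [8, 9) s; its mean is 8.5 - dt/2
        expected_first = 10.0 - (8.5 - 0.5 / fs)
        assert out.epochs[0, 0, 0] == pytest.approx(expected_first, abs=1e-9)

    def test_missing_baseline_trial_dropped(self):
        rec = flat_recording(seconds=20.0,
                             markers=[Marker(1.0, TASK_MARKER_PREFIX + "arrow_left"),
                                      Marker(10.0, TASK_MARKER_PREFIX + "arrow_left")])
        eps = epoch(rec, {"arrow_left": "left_mi"})
        with pytest.warns(UserWarning, match="baseline"):
            out = baseline_correct(eps)
        assert out.n_trials == 1


class TestNormalization:
    def test_single_session_zscore(self):
        eps = self._two_session_eps(single=True)
        out = normalize_sessions(eps)
        assert abs(out.epochs.mean()) < 1e-9
        assert out.epochs.std(axis=(0, 2)) == pytest.approx(np.ones(2))

    def test_two_sessions_centered(self):
        out = normalize_sessions(self._two_session_eps())
        for sess in ("s1", "s2"):
            sel = out.session_ids == sess
            assert abs(out.epochs[sel].mean()) < 1e-9

    def test_stored_stats_reapply(self):
        eps = self._two_session_eps()
        out = normalize_sessions(eps)
        mean, sd = out.normalization_stats["s1"]
        sel = eps.session_ids == "s1"
        again = apply_normalization(eps.epochs[sel], (mean, sd))
        assert np.allclose(again, out.epochs[sel])

    def test_constant_channel_floored(self):
        eps = self._two_session_eps(single=True)
        eps.epochs[:, 1, :] = 3.14
        with pytest.warns(UserWarning, match="floored"):
            out = normalize_sessions(eps)
        assert np.all(np.isfinite(out.epochs))

    @staticmethod
    def _two_session_eps(single=False):
        rng = np.random.default_rng(2)
        from mibci.containers import EpochSet
        n = 6
        data = rng.standard_normal((n, 2, 100))
        data[3:] += 10.0
        sessions = np.array(["s1"] * n if single else ["s1"] * 3 + ["s2"] * 3)
        return EpochSet(epochs=data, labels=np.array(["a", "b", "a", "b", "a", "b"]),
                        tmin=0.0, tmax=0.4, fs=FS, channel_names=["c1", "c2"],
                        session_ids=sessions)


class TestOfflineOnlineAgreement:
    def test_streaming_chain_matches_batch(self):
        """Filter + ASR + CAR over 100 ms chunks equals the batch chain."""
        sim = SimConfig(seed=21)
        rec = generate_recording(sim, ParadigmSpec(trials_per_class=2))
        calib = generate_calibration(sim)
        pre = OfflinePreprocessor().fit(calib)
        batch = pre.filter_.filter_batch(rec.data)
        from mibci.preprocess.asr import apply_asr
        batch = common_average_reference(apply_asr(batch, pre.asr_))

        stream = StreamingPreprocessor.from_offline(pre)
        outs = []
        step = 25
        for s in range(0, rec.n_samples, step):
            outs.append(stream.process(rec.data[:, s:s + step]))
        outs.append(stream.flush())
        streamed = np.concatenate([o for o in outs if o.size], axis=1)
        assert streamed.shape == batch.shape
        warm = pre.asr_.window_samples
        rms = np.sqrt(np.mean((streamed[:, warm:] - batch[:, warm:]) ** 2))
        assert rms < 1e-6

    def test_full_offline_pipeline_on_synthetic(self):
        sim = SimConfig(seed=22)
        par = ParadigmSpec(trials_per_class=3)
        rec = generate_recording(sim, par)
        calib = generate_calibration(sim)
        eps = preprocess_recordings([rec], calib, par.cue_to_class())
        assert eps.n_trials + eps.dropped == 9
        assert eps.normalization_stats is not None
        assert set(eps.classes) == {"rest", "left_mi", "right_mi"}
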