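"""Replay, transfer function, control mapping, latency stats, ITR, pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mibci.containers import RawRecording
from mibci.realtime.latency import (ITRQuery, compute_itr,
                                    itr_bits_per_selection, latency_summary,
                                    nearest_rank_percentile)
from mibci.realtime.pipeline import BoundedQueue, replay, run_pipeline
from mibci.realtime.transfer import (NEUTRAL, TransferConfig, TransferState,
                                     map_controls, transfer_update)

FS = 250.0


class TestReplay:
    def test_chunk_counts(self):
        rec = RawRecording(data=np.zeros((2, 15000)), fs=FS,
                           channel_names=["a", "b"])
        chunks = list(replay(rec, chunk_ms=100))
        assert len(chunks) == 600
        assert all(c.samples.shape == (2, 25) for c in chunks)

    def test_bit_exact_concatenation(self, rng):
        rec = RawRecording(data=rng.standard_normal((3, 1013)), fs=FS,
                           channel_names=list("abc"))
        cat = np.concatenate([c.samples for c in replay(rec, chunk_ms=100)],
                             axis=1)
        assert np.array_equal(cat, rec.data)

    def test_timestamps_monotone(self):
        rec = RawRecording(data=np.zeros((1, 1000)), fs=FS, channel_names=["a"])
        times = [c.first_sample_time for c in replay(rec, chunk_ms=40)]
        assert np.all(np.diff(times) > 0)

    def test_bad_chunk_ms(self):
        rec = RawRecording(data=np.zeros((1, 100)), fs=FS, channel_names=["a"])
        with pytest.raises(ValueError):
            list(replay(rec, chunk_ms=0))


class TestTransferUpdate:
    def _cfg(self, **kw):
        return TransferConfig(**kw)

    def test_one_hot_buffer_decides_class(self):
        cfg = self._cfg()
        st_ = TransferState.fresh(cfg)
        for _ in range(10):
            st_, d = transfer_update(st_, np.array([1.0, 0.0, 0.0]), cfg)
        assert d == "rest"

    def test_uniform_is_neutral(self):
        cfg = self._cfg()
        st_ = TransferState.fresh(cfg)
        st_, d = transfer_update(st_, np.ones(3) / 3, cfg)
        assert d == NEUTRAL

    def test_tie_breaks_to_lowest_index(self):
        """buffer_len=4 with [1,0,0] x2 then [0,1,0] x2: mean (.5,.5,0)."""
        cfg = self._cfg(buffer_len=4)
        st_ = TransferState.fresh(cfg)
        for v in ([1, 0, 0], [1, 0, 0], [0, 1, 0], [0, 1, 0]):
            st_, d = transfer_update(st_, np.array(v, dtype=float), cfg)
        assert d == "rest"  # class index 0 wins the tie at threshold 0.5

    def test_malformed_probs_rejected(self):
        cfg = self._cfg()
        st_ = TransferState.fresh(cfg)
        with pytest.raises(ValueError):
            transfer_update(st_, np.array([0.9, 0.9, 0.9]), cfg)
        with pytest.raises(ValueError):
            transfer_update(st_, np.array([0.5, 0.5]), cfg)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.integers(0, 2), min_size=12, max_size=30))
    def test_decision_depends_only_on_buffer(self, seq):
        """The decision is a pure function of the last buffer_len vectors."""
        cfg = self._cfg(buffer_len=5)
        onehot = np.eye(3)
        st_ = TransferState.fresh(cfg)
        for c in seq:
            st_, d = transfer_update(st_, onehot[c], cfg)
        st2 = TransferState.fresh(cfg)
        for c in seq[-5:]:
            st2, d2 = transfer_update(st2, onehot[c], cfg)
        assert d == d2


class TestMapControls:
    def _cfg(self):
        return TransferConfig(mapping={"rest": "neutral", "left_mi": "x-",
                                       "right_mi": "a"},
                              binary_fill_rate=0.25, binary_decay_rate=0.25)

    def test_binary_fires_on_fourth_tick(self):
        cfg = self._cfg()
        st_ = TransferState.fresh(cfg)
        fires = []
        for t in range(4):
            frame, st_ = map_controls("right_mi", cfg, st_, t)
            fires.append(frame.a)
        assert fires == [0, 0, 0, 1]
        assert st_.fill_a == 0.0  # reset after firing

    def test_alternating_never_fires(self):
        cfg = self._cfg()
        st_ = TransferState.fresh(cfg)
        for t in range(20):
            decision = "right_mi" if t % 2 == 0 else "left_mi"
            frame, st_ = map_controls(decision, cfg, st_, t)
            assert frame.a == 0

    def test_neutral_forever_all_zero(self):
        cfg = self._cfg()
        st_ = TransferState.fresh(cfg)
        for t in range(5):
            frame, st_ = map_controls(NEUTRAL, cfg, st_, t)
            assert (frame.x, frame.y, frame.a, frame.b) == (0.0, 0.0, 0, 0)

    def test_axis_mapping(self):
        cfg = self._cfg()
        frame, _ = map_controls("left_mi", cfg, TransferState.fresh(cfg), 0)
        assert frame.x == -1.0 and frame.y == 0.0

    def test_unmapped_class(self):
        cfg = self._cfg()
        with pytest.raises(ValueError, match="unmapped"):
            map_controls("jump", cfg, TransferState.fresh(cfg), 0)


class TestLatencySummary:
    def _entries(self, deltas, n):
        out = []
        for i in range(n):
            a = float(i)
            out.append({"acquisition_t": a, "preprocess_t": a + deltas[0],
                        "classify_t": a + deltas[0] + deltas[1],
                        "transfer_t": a + sum(deltas)})
        return out

    def test_constant_deltas(self):
        s = latency_summary(self._entries([0.010, 0.020, 0.005], 10))
        assert s["preprocess"]["median"] == pytest.approx(10.0)
        assert s["classify"]["median"] == pytest.approx(20.0)
        assert s["transfer"]["median"] == pytest.approx(5.0)
        assert s["total"]["median"] == pytest.approx(35.0)

    def test_nearest_rank_p95(self, rng):
        vals = rng.random(100)
        expected = np.sort(vals)[94]  # ceil(0.95*100) = 95th order statistic
        assert nearest_rank_percentile(vals, 95) == expected

    def test_single_record(self):
        s = latency_summary(self._entries([0.001, 0.002, 0.003], 1))
        assert s["total"]["median"] == s["total"]["p95"] == s["total"]["p99"]

    def test_empty_log(self):
        with pytest.raises(ValueError):
            latency_summary([])


class TestITR:
    @pytest.mark.parametrize("T,expected", [(1.617, 17.57), (3.117, 9.11),
                                            (4.617, 6.15)])
    def test_published_operating_points(self, T, expected):
        assert compute_itr(ITRQuery(3, 0.73, T)) == pytest.approx(expected,
                                                                  abs=0.01)

    def test_chance_level_zero(self):
        assert compute_itr(ITRQuery(3, 1 / 3, 2.0)) == pytest.approx(0.0,
                                                                     abs=1e-12)

    def test_perfect_accuracy(self):
        assert compute_itr(ITRQuery(3, 1.0, 60.0)) == pytest.approx(
            np.log2(3), abs=1e-12)

    def test_matches_mutual_information_oracle(self):
        """B equals the mutual information of the symmetric-confusion channel
        with uniform input."""
        for N, P in [(2, 0.9), (3, 0.73), (4, 0.5), (5, 0.21)]:
            px = 1.0 / N
            mi = 0.0
            for xi in range(N):
                for yi in range(N):
                    pyx = P if xi == yi else (1 - P) / (N - 1)
                    py = sum(px * (P if xj == yi else (1 - P) / (N - 1))
                             for xj in range(N))
                    if pyx > 0:
                        mi += px * pyx * np.log2(pyx / py)
            assert itr_bits_per_selection(N, P) == pytest.approx(mi, abs=1e-12)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.floats(0.01, 0.99))
    def test_minimum_at_chance(self, P):
        b = itr_bits_per_selection(3, P)
        assert b >= -1e-12
        assert b >= itr_bits_per_selection(3, 1 / 3) - 1e-12

    def test_invalid_queries(self):
        with pytest.raises(ValueError):
            ITRQuery(1, 0.5, 1.0)
        with pytest.raises(ValueError):
            ITRQuery(3, 1.5, 1.0)
        with pytest.raises(ValueError):
            ITRQuery(3, 0.5, 0.0)


class TestBoundedQueue:
    def test_drop_oldest_and_count(self):
        q = BoundedQueue(maxsize=3)
        for i in range(5):
            q.put(i)
        assert q.dropped == 2
        assert [q.get(), q.get(), q.get()] == [2, 3, 4]


class TestRunPipeline:
    def _setup(self):
        from mibci.model.s4d import S4DConfig, S4DNetwork
        from mibci.preprocess.chain import (OfflinePreprocessor,
                                            StreamingPreprocessor)
        from mibci.synthdata import SimConfig, generate_calibration
        sim = SimConfig(seed=31)
        calib = generate_calibration(sim)
        pre = OfflinePreprocessor().fit(calib)
        net = S4DNetwork(S4DConfig(hidden_dim=8, num_layers=1,
                                   dropout_rate=0.0, state_dim=8),
                         n_features=288, seed=0)
        return sim, pre, net

    def test_empty_stream_clean_shutdown(self):
        _, pre, net = self._setup()
        from mibci.preprocess.chain import StreamingPreprocessor
        res = run_pipeline(iter(()), StreamingPreprocessor.from_offline(pre),
                           net, TransferConfig(), csp=None, fs=FS)
        assert res.control_frames == []
        assert res.dropped_chunks == 0

    def test_spec_hash_mismatch_refuses(self):
        sim, pre, net = self._setup()
        from mibci.preprocess.chain import StreamingPreprocessor
        from mibci.synthdata import generate_calibration
        rec = generate_calibration(sim, duration=5.0)
        with pytest.raises(ValueError, match="hash"):
            run_pipeline(replay(rec), StreamingPreprocessor.from_offline(pre),
                         net, TransferConfig(), csp=None, fs=FS,
                         expected_spec_hash="deadbeef")

    def test_stamps_monotone_and_no_drops(self):
        sim, pre, net = self._setup()
        from mibci.preprocess.chain import StreamingPreprocessor
        from mibci.synthdata import generate_calibration
        rec = generate_calibration(sim, duration=8.0, session_id="replay")
        res = run_pipeline(replay(rec), StreamingPreprocessor.from_offline(pre),
                           net, TransferConfig(), csp=None, fs=FS, hop_s=0.5)
        assert res.dropped_chunks == 0
        assert len(res.control_frames) > 0
        for entry in res.latency_log:
            assert (entry["acquisition_t"] <= entry["preprocess_t"]
                    <= entry["classify_t"] <= entry["transfer_t"])

    def test_threaded_mode_matches_synchronous(self):
        sim, pre, net = self._setup()
        from mibci.preprocess.chain import StreamingPreprocessor
        from mibci.synthdata import generate_calibration
        rec = generate_calibration(sim, duration=6.0)
        kw = dict(model=net, transfer=TransferConfig(), csp=None, fs=FS,
                  hop_s=0.5)
        r1 = run_pipeline(replay(rec),
                          StreamingPreprocessor.from_offline(pre), **kw)
        r2 = run_pipeline(replay(rec),
                          StreamingPreprocessor.from_offline(pre),
                          threaded=True, **kw)
        assert np.allclose(r1.window_probs, r2.window_probs)
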