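"""Replay-driven online pipeline: acquisition -> preprocess -> classify ->
transfer, as independent stages joined by bounded drop-oldest queues.

The default scheduler is synchronous: it pumps the same queues in stage
order, which is deterministic and reproduces the batch pipeline exactly —
the property the offline/online equivalence check relies on. A threaded
mode runs each stage in its own thread behind the identical queue contract,
with a watchdog for stalled stages.

Every control frame carries the four stage timestamps (acquisition,
preprocess, classify, transfer) for latency analysis, and a feedback-state
stream publishes the smoothed per-class probabilities, thresholds and
binary fill levels driving the user feedback screen.
"""

from __future__ import annotations

import time
from collections import deque
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Iterator

import numpy as np

from ..containers import RawRecording
from ..features import (CSP, MorletSpec, extract_features, feature_spec_hash,
                        morlet_power, stack_features)
from ..preprocess.chain import StreamingPreprocessor, apply_normalization, \
    common_average_reference
from ..preprocess.asr import apply_asr
from .transfer import ControlFrame, TransferConfig, TransferState, \
    map_controls, transfer_update

__all__ = ["StreamChunk", "StageMessage", "replay", "run_pipeline",
           "PipelineResult", "window_probabilities"]


@dataclass
class StreamChunk:
    samples: np.ndarray          # (channels, n)
    first_sample_time: float     # seconds from stream start
    fs: float


@dataclass
class StageMessage:
    payload: Any
    stamps: dict[str, float] = field(default_factory=dict)

    def stamped(self, name: str, t: float) -> "StageMessage":
        stamps = dict(self.stamps)
        stamps[name] = t
        return StageMessage(self.payload, stamps)


def replay(rec: RawRecording, chunk_ms: float = 100.0,
           pacing: bool = False) -> Iterator[StreamChunk]:
    """Contiguous, gapless chunks covering the recording.

    With ``pacing`` the generator sleeps one chunk period per chunk;
    otherwise it runs as fast as the consumer pulls.
    """
    if chunk_ms <= 0:
        raise ValueError("chunk_ms must be > 0")
    n = max(int(round(chunk_ms / 1000.0 * rec.fs)), 1)
    for start in range(0, rec.n_samples, n):
        if pacing:
            time.sleep(chunk_ms / 1000.0)
        yield StreamChunk(rec.data[:, start:start + n], start / rec.fs, rec.fs)


class BoundedQueue:
    """Order-preserving, non-blocking; drops the *oldest* entry on overflow."""

    def __init__(self, maxsize: int = 256):
        self._q: deque = deque()
        self.maxsize = maxsize
        self.dropped = 0

    def put(self, item) -> None:
        if len(self._q) >= self.maxsize:
            self._q.popleft()
            self.dropped += 1
        self._q.append(item)

    def get(self):
        return self._q.popleft() if self._q else None

    def __len__(self):
        return len(self._q)


@dataclass
class PipelineResult:
    control_frames: list[ControlFrame]
    latency_log: list[dict]
    feedback_states: list[dict]
    window_probs: np.ndarray       # (n_windows, n_classes)
    window_starts: np.ndarray      # sample index of each window start
    dropped_chunks: int


class _PreprocessStage:
    def __init__(self, streaming: StreamingPreprocessor):
        self.streaming = streaming

    def process(self, msg: StageMessage) -> list[StageMessage]:
        cleaned = self.streaming.process(msg.payload.samples)
        if cleaned.shape[1] == 0:
            return []
        return [StageMessage(cleaned, dict(msg.stamps))]

    def flush(self) -> list[StageMessage]:
        cleaned = self.streaming.flush()
        if cleaned.shape[1] == 0:
            return []
        return [StageMessage(cleaned, {})]


class _ClassifyStage:
    """Buffers cleaned samples; classifies a sliding window every hop."""

    def __init__(self, model, morlet: MorletSpec | None, csp: CSP | None,
                 norm_stats, window_samples: int, hop_samples: int):
        self.model = model
        self.morlet = morlet
        self.csp = csp
        self.norm_stats = norm_stats
        self.window = window_samples
        self.hop = hop_samples
        self._buffer: np.ndarray | None = None
        self._next_start = 0
        self._consumed = 0    # samples discarded from the buffer front
        self.fs: float | None = None

    def _features(self, window: np.ndarray, fs: float) -> np.ndarray:
        w = window[None, :, :]
        if self.norm_stats is not None:
            w = apply_normalization(w, self.norm_stats)
        mp = morlet_power(w, fs=fs, spec=self.morlet) if self.morlet else None
        cf = self.csp.transform(w) if self.csp is not None else None
        ft = stack_features(mp, cf, labels=np.array(["?"]),
                            trial_ids=np.array([0]))
        return ft.data

    def process(self, msg: StageMessage, fs: float) -> list[StageMessage]:
        block = msg.payload
        self._buffer = block if self._buffer is None else np.concatenate(
            [self._buffer, block], axis=1)
        out = []
        while True:
            start_rel = self._next_start - self._consumed
            if start_rel + self.window > self._buffer.shape[1]:
                break
            win = self._buffer[:, start_rel:start_rel + self.window]
            probs = self.model.predict_proba(self._features(win, fs))[0]
            out.append(StageMessage(
                {"probs": probs, "window_start": self._next_start},
                dict(msg.stamps)))
            self._next_start += self.hop
        # trim everything before the next window start
        drop = (self._next_start - self._consumed)
        if drop > 0 and self._buffer.shape[1] > 0:
            drop = min(drop, self._buffer.shape[1])
            self._buffer = self._buffer[:, drop:]
            self._consumed += drop
        return out


class _TransferStage:
    def __init__(self, config: TransferConfig):
        self.config = config
        self.state = TransferState.fresh(config)
        self.tick = 0

    def process(self, msg: StageMessage) -> tuple[StageMessage, dict]:
        probs = msg.payload["probs"]
        self.state, decision = transfer_update(self.state, probs, self.config)
        frame, self.state = map_controls(decision, self.config, self.state,
                                         self.tick)
        feedback = {
            "tick": self.tick,
            "decision": decision,
            "smoothed_probs": np.mean(self.state.buffer, axis=0).tolist(),
            "thresholds": dict(self.config.class_thresholds),
            "fills": {"a": self.state.fill_a, "b": self.state.fill_b},
        }
        self.tick += 1
        return StageMessage({"frame": frame, **msg.payload},
                            dict(msg.stamps)), feedback


def run_pipeline(stream: Iterable[StreamChunk],
                 streaming_pre: StreamingPreprocessor,
                 model,
                 transfer: TransferConfig,
                 morlet: MorletSpec | None = MorletSpec(),
                 csp: CSP | None = None,
                 normalization_stats=None,
                 window_s: float = 1.0,
                 hop_s: float = 0.1,
                 fs: float = 250.0,
                 expected_spec_hash: str | None = None,
                 queue_size: int = 4096,
                 threaded: bool = False,
                 watchdog_s: float = 30.0,
                 clock: Callable[[], float] = time.perf_counter
                 ) -> PipelineResult:
    """Drive the full online chain over a chunk stream.

    If ``expected_spec_hash`` (from a model checkpoint) is given, it must
    match the hash of the configured feature extraction or the pipeline
    refuses to start.
    """
    window_samples = int(round(window_s * fs))
    hop_samples = max(int(round(hop_s * fs)), 1)
    n_ch = streaming_pre.asr_stream.model.n_channels
    actual_hash = feature_spec_hash(
        morlet, n_ch, 0 if csp is None else csp.filters_.shape[0],
        window_samples)
    if expected_spec_hash is not None and expected_spec_hash != actual_hash:
        raise ValueError(
            f"feature spec hash mismatch: model expects {expected_spec_hash}, "
            f"configuration computes {actual_hash}"
        )

    pre = _PreprocessStage(streaming_pre)
    clf = _ClassifyStage(model, morlet, csp, normalization_stats,
                         window_samples, hop_samples)
    tf = _TransferStage(transfer)

    frames: list[ControlFrame] = []
    latency_log: list[dict] = []
    feedback: list[dict] = []
    probs_out: list[np.ndarray] = []
    starts_out: list[int] = []

    q_in = BoundedQueue(queue_size)
    q_pre = BoundedQueue(queue_size)
    q_clf = BoundedQueue(queue_size)

    def pump_pre():
        while True:
            msg = q_pre.get()
            if msg is None:
                return
            for m in pre.process(msg):
                q_clf.put(m.stamped("preprocess_t", clock()))

    def pump_clf_tf():
        while True:
            msg = q_clf.get()
            if msg is None:
                return
            for m in clf.process(msg, fs):
                m = m.stamped("classify_t", clock())
                out, fb = tf.process(m)
                out = out.stamped("transfer_t", clock())
                frames.append(out.payload["frame"])
                feedback.append(fb)
                probs_out.append(out.payload["probs"])
                starts_out.append(out.payload["window_start"])
                if all(k in out.stamps for k in
                       ("acquisition_t", "preprocess_t",
                        "classify_t", "transfer_t")):
                    latency_log.append(dict(out.stamps))

    if threaded:
        import threading

        stop = object()
        done = threading.Event()

        def worker():
            while True:
                msg = q_in.get()
                if msg is stop:
                    for m in pre.flush():
                        q_clf.put(m.stamped("preprocess_t", clock()))
                    pump_clf_tf()
                    done.set()
                    return
                if msg is None:
                    time.sleep(1e-4)
                    continue
                q_pre.put(msg)
                pump_pre()
                pump_clf_tf()

        th = threading.Thread(target=worker, daemon=True)
        th.start()
        for chunk in stream:
            q_in.put(StageMessage(chunk).stamped("acquisition_t", clock()))
        q_in.put(stop)
        if not done.wait(timeout=watchdog_s):
            raise TimeoutError(f"pipeline stage stalled (> {watchdog_s}s)")
        th.join(timeout=watchdog_s)
    else:
        for chunk in stream:
            q_in.put(StageMessage(chunk).stamped("acquisition_t", clock()))
            while True:
                msg = q_in.get()
                if msg is None:
                    break
                q_pre.put(msg)
                pump_pre()
                pump_clf_tf()
        for m in pre.flush():
            q_clf.put(m.stamped("preprocess_t", clock()))
        pump_clf_tf()

    return PipelineResult(
        control_frames=frames, latency_log=latency_log,
        feedback_states=feedback,
        window_probs=np.array(probs_out) if probs_out else np.empty((0, 0)),
        window_starts=np.array(starts_out, dtype=int),
        dropped_chunks=q_in.dropped + q_pre.dropped + q_clf.dropped,
    )


def window_probabilities(rec: RawRecording, filt, asr_model, model,
                         morlet: MorletSpec | None = MorletSpec(),
                         csp: CSP | None = None,
                         normalization_stats=None,
                         window_s: float = 1.0,
                         hop_s: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Batch reference for the online path: filter -> ASR -> CAR on the whole
    recording, then classify the same sliding-window grid in one shot.

    Returns (window start sample indices, per-window class probabilities).
    """
    y = filt.filter_batch(rec.data)
    y = apply_asr(y, asr_model)
    y = common_average_reference(y)
    fs = rec.fs
    W = int(round(window_s * fs))
    H = max(int(round(hop_s * fs)), 1)
    starts = np.arange(0, y.shape[1] - W + 1, H)
    wins = np.stack([y[:, s:s + W] for s in starts])
    if normalization_stats is not None:
        wins = apply_normalization(wins, normalization_stats)
    mp = morlet_power(wins, fs=fs, spec=morlet) if morlet else None
    cf = csp.transform(wins) if csp is not None else None
    ft = stack_features(mp, cf, labels=np.array(["?"] * len(wins)),
                        trial_ids=np.arange(len(wins)))
    probs = model.predict_proba(ft.data)
    return starts, probs
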