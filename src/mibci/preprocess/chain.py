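"""Offline and streaming preprocessing chains.

Order of operations (identical in both modes): band-pass filter -> head crop
(offline only) -> channel rejection (offline only; the online chain uses the
channel set frozen at fit time) -> artifact subspace reconstruction ->
common average reference. Offline, the chain then epochs on task-onset
markers, baseline-corrects against the pre-cue interval, and z-scores per
(session, channel).

The offline chain compensates the filter's fixed 0.5 s latency by advancing
the filtered signal before epoching, so epochs stay aligned with markers.
The streaming chain cannot look ahead, so its output is simply delayed by
that latency — the same methodological delay the live system pays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ..containers import EpochSet, Marker, RawRecording
from ..synthdata import TASK_MARKER_PREFIX
from .asr import ASRModel, ASRStream, apply_asr, fit_asr
from .filtering import BandpassFilter, FilterSpec, design_filter

__all__ = [
    "ChannelRejectRules", "PreprocessConfig", "OfflinePreprocessor",
    "StreamingPreprocessor", "baseline_correct", "common_average_reference",
    "crop_head", "epoch", "normalize_sessions", "apply_normalization",
    "reject_channels",
]

SD_FLOOR = 1e-12


@dataclass(frozen=True)
class ChannelRejectRules:
    """Thresholds for the extreme-artifact channel categories:
    flatlines, excessive noise, non-physiological spikes."""

    flatline_sd_floor: float = 0.1     # µV
    noise_ratio_cap: float = 5.0       # x median robust SD
    spike_amplitude_cap: float = 500.0  # µV

    def __post_init__(self) -> None:
        if min(self.flatline_sd_floor, self.noise_ratio_cap,
               self.spike_amplitude_cap) <= 0:
            raise ValueError("all rejection thresholds must be > 0")


def crop_head(rec: RawRecording, seconds: float = 10.0) -> RawRecording:
    """Drop the first ``seconds`` (filter adaptation); shift markers."""
    if rec.duration <= seconds:
        raise ValueError(
            f"recording is {rec.duration:.1f}s; cannot crop {seconds}s"
        )
    n0 = int(round(seconds * rec.fs))
    markers = [Marker(m.onset - seconds, m.label)
               for m in rec.markers if m.onset - seconds >= 0]
    return RawRecording(data=rec.data[:, n0:].copy(), fs=rec.fs,
                        channel_names=list(rec.channel_names),
                        markers=markers, session_id=rec.session_id)


def reject_channels(rec: RawRecording,
                    rules: ChannelRejectRules = ChannelRejectRules()
                    ) -> tuple[RawRecording, list[str]]:
    """Remove flatline / noisy / spiking channels, preserving survivor order."""
    if rec.n_channels < 2:
        raise ValueError("need >= 2 channels")
    X = rec.data
    sd = X.std(axis=1)
    robust_sd = 1.4826 * np.median(np.abs(X - np.median(X, axis=1, keepdims=True)),
                                   axis=1)
    med_robust = np.median(robust_sd)
    peak = np.max(np.abs(X), axis=1)
    bad = (
        (sd < rules.flatline_sd_floor)
        | (robust_sd > rules.noise_ratio_cap * max(med_robust, SD_FLOOR))
        | (peak > rules.spike_amplitude_cap)
    )
    rejected = [rec.channel_names[i] for i in np.flatnonzero(bad)]
    if len(rejected) == rec.n_channels:
        raise ValueError("all channels rejected; recording unusable")
    keep = ~bad
    kept = RawRecording(data=X[keep].copy(), fs=rec.fs,
                        channel_names=[c for c, k in zip(rec.channel_names, keep) if k],
                        markers=list(rec.markers), session_id=rec.session_id)
    return kept, rejected


def common_average_reference(data: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous cross-channel mean (applied after ASR so
    the rank reduction happens last)."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("need a (channels x samples) array with >= 2 channels")
    return data - data.mean(axis=0, keepdims=True)


def epoch(rec: RawRecording, mapping: dict[str, str], tmin: float = 0.0,
          tmax: float = 3.0, pre_window: float = 2.0) -> EpochSet:
    """One epoch per task-onset marker, time-locked to task onset.

    ``mapping`` maps cue labels (the on-screen symbols) to class names; task
    markers carry the ``task:`` prefix plus the cue label. Each epoch covers
    [tmin, tmax); ``pre_window`` seconds before task onset are captured
    alongside for later baseline correction (NaN where unavailable). Trials
    whose window runs past the recording are dropped and counted.
    """
    if not rec.markers:
        raise ValueError("recording has no markers")
    n_pre = int(round(pre_window * rec.fs))
    i_min = int(round(tmin * rec.fs))
    i_max = int(round(tmax * rec.fs))
    epochs, labels, baselines = [], [], []
    dropped = 0
    unmapped = 0
    for m in rec.markers:
        if not m.label.startswith(TASK_MARKER_PREFIX):
            continue
        cue_label = m.label[len(TASK_MARKER_PREFIX):]
        if cue_label not in mapping:
            unmapped += 1
            continue
        onset = int(round(m.onset * rec.fs))
        lo, hi = onset + i_min, onset + i_max
        if lo < 0 or hi > rec.n_samples:
            dropped += 1
            continue
        epochs.append(rec.data[:, lo:hi])
        labels.append(mapping[cue_label])
        bl = np.full((rec.n_channels, n_pre), np.nan)
        b_lo = onset - n_pre
        if b_lo >= 0:
            bl[:] = rec.data[:, b_lo:onset]
        baselines.append(bl)
    if not epochs:
        raise ValueError("no mappable task markers produced epochs")
    if unmapped:
        warnings.warn(f"{unmapped} task markers had unmapped cue labels",
                      stacklevel=2)
    return EpochSet(
        epochs=np.stack(epochs), labels=np.array(labels), tmin=tmin, tmax=tmax,
        fs=rec.fs, channel_names=list(rec.channel_names),
        session_ids=np.array([rec.session_id] * len(labels)),
        baseline_data=np.stack(baselines), dropped=dropped,
    )


def baseline_correct(epochs: EpochSet, baseline: tuple[float, float] = (-1.0, 0.0),
                     cue_duration: float = 1.0) -> EpochSet:
    """Subtract the per-trial per-channel mean over the pre-cue baseline.

    ``baseline`` is relative to *cue onset* (default [-1, 0) s: the second
    before the cue appears); epochs are locked to task onset, which trails
    the cue by ``cue_duration``. Trials without recorded baseline samples
    are dropped with a warning count.
    """
    if epochs.baseline_data is None:
        raise ValueError("epoch set carries no pre-task baseline data")
    b0, b1 = baseline
    if b1 <= b0:
        raise ValueError("empty baseline interval")
    n_pre = epochs.baseline_data.shape[2]
    # convert cue-relative -> task-relative -> index into the pre-task buffer
    i0 = n_pre + int(round((b0 - cue_duration) * epochs.fs))
    i1 = n_pre + int(round((b1 - cue_duration) * epochs.fs))
    if i0 < 0 or i1 > n_pre or i1 <= i0:
        raise ValueError(
            f"baseline {baseline} (cue-relative) outside the captured "
            f"{n_pre / epochs.fs:.2f}s pre-task window"
        )
    seg = epochs.baseline_data[:, :, i0:i1]
    ok = np.all(np.isfinite(seg), axis=(1, 2))
    n_drop = int(np.sum(~ok))
    if n_drop:
        warnings.warn(f"{n_drop} trials lacked baseline samples and were dropped",
                      stacklevel=2)
    means = seg[ok].mean(axis=2, keepdims=True)
    return epochs.copy_with(
        epochs=epochs.epochs[ok] - means,
        labels=epochs.labels[ok],
        session_ids=epochs.session_ids[ok],
        trial_ids=epochs.trial_ids[ok],
        baseline_data=epochs.baseline_data[ok],
        dropped=epochs.dropped + n_drop,
    )


def normalize_sessions(epochs: EpochSet) -> EpochSet:
    """Z-score per (session, channel), pooling each session's epochs.

    Stores the statistics in ``normalization_stats`` so the online pipeline
    can reuse them; constant channels get an SD floor of 1e-12 and a warning.
    """
    out = epochs.epochs.copy()
    stats: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    flagged = []
    for sess in np.unique(epochs.session_ids):
        sel = epochs.session_ids == sess
        block = epochs.epochs[sel]                     # trials x ch x time
        mean = block.mean(axis=(0, 2))
        sd = block.std(axis=(0, 2))
        low = sd < SD_FLOOR
        if np.any(low):
            flagged.extend(np.array(epochs.channel_names)[low].tolist())
            sd = np.where(low, SD_FLOOR, sd)
        out[sel] = (block - mean[None, :, None]) / sd[None, :, None]
        stats[str(sess)] = (mean, sd)
    if flagged:
        warnings.warn(f"constant channels floored during normalization: {flagged}",
                      stacklevel=2)
    return epochs.copy_with(epochs=out, normalization_stats=stats)


def apply_normalization(data: np.ndarray, stats: tuple[np.ndarray, np.ndarray]
                        ) -> np.ndarray:
    """Apply stored (mean, sd) per-channel statistics to (.., ch, time) data."""
    mean, sd = stats
    return (data - mean[..., :, None]) / sd[..., :, None]


@dataclass
class PreprocessConfig:
    """Everything the chain needs besides the data itself."""

    filter_spec: FilterSpec | None = None    # default built from fs at fit time
    crop_seconds: float = 10.0
    reject_rules: ChannelRejectRules = field(default_factory=ChannelRejectRules)
    asr_threshold_k: float = 3.0
    asr_max_dropout_fraction: float = 0.4
    asr_window_length: float = 0.5
    epoch_tmin: float = 0.0
    epoch_tmax: float = 3.0
    baseline: tuple[float, float] = (-1.0, 0.0)   # cue-relative
    cue_duration: float = 1.0


class OfflinePreprocessor:
    """Batch chain: calibrate once, then turn recordings into epoch sets."""

    def __init__(self, config: PreprocessConfig | None = None):
        self.config = config or PreprocessConfig()
        self.filter_: BandpassFilter | None = None
        self.asr_: ASRModel | None = None
        self.channel_names_: list[str] | None = None

    def fit(self, calibration: RawRecording,
            channel_names: list[str] | None = None) -> "OfflinePreprocessor":
        """Design the filter and fit ASR statistics on the calibration minute.

        ``channel_names`` restricts to the post-rejection channel set when
        known; otherwise all calibration channels are used.
        """
        cfg = self.config
        spec = cfg.filter_spec or FilterSpec(fs=calibration.fs)
        if spec.fs != calibration.fs:
            raise ValueError("filter spec fs does not match calibration fs")
        self.filter_ = design_filter(spec)
        calib = calibration
        if channel_names is not None:
            idx = [calib.channel_index(c) for c in channel_names]
            calib = calib.copy_with(data=calib.data[idx],
                                    channel_names=list(channel_names))
        self.channel_names_ = list(calib.channel_names)
        filtered = self.filter_.filter_batch(calib.data)
        # discard filter warm-up (latency + settling) before fitting statistics
        skip = int(round(2.0 * calib.fs))
        self.asr_ = fit_asr(
            calib.copy_with(data=filtered[:, skip:], markers=[]),
            threshold_k=cfg.asr_threshold_k,
            max_dropout_fraction=cfg.asr_max_dropout_fraction,
            window_length=cfg.asr_window_length,
        )
        return self

    def _check_fitted(self):
        if self.filter_ is None or self.asr_ is None:
            raise RuntimeError("preprocessor is not fitted; call fit() first")

    def clean_continuous(self, rec: RawRecording, crop: bool = True,
                         compensate_latency: bool = True) -> RawRecording:
        """Filter -> (crop) -> ASR -> CAR on an already channel-subset recording."""
        self._check_fitted()
        if rec.channel_names != self.channel_names_:
            raise ValueError("recording channels differ from the fitted set")
        y = self.filter_.filter_batch(rec.data)
        if compensate_latency and self.filter_.delay_samples:
            d = self.filter_.delay_samples
            y = y[:, d:]
        clean = rec.copy_with(data=y, markers=[m for m in rec.markers
                                               if m.onset <= y.shape[1] / rec.fs])
        if crop:
            clean = crop_head(clean, self.config.crop_seconds)
        cleaned = apply_asr(clean.data, self.asr_)
        cleaned = common_average_reference(cleaned)
        return clean.copy_with(data=cleaned)

    def process(self, rec: RawRecording, mapping: dict[str, str]) -> EpochSet:
        """Full chain for one recording: continuous cleaning then epoching
        and baseline correction (session normalization is applied across
        recordings by :func:`preprocess_recordings`)."""
        cfg = self.config
        rec, _rejected = reject_channels(rec, cfg.reject_rules)
        if rec.channel_names != self.channel_names_:
            # refit calibration statistics on the surviving channel set
            raise RuntimeError(
                "channel set changed after rejection; refit the preprocessor "
                f"with channel_names={rec.channel_names}"
            )
        clean = self.clean_continuous(rec)
        eps = epoch(clean, mapping, cfg.epoch_tmin, cfg.epoch_tmax,
                    pre_window=cfg.cue_duration - cfg.baseline[0])
        return baseline_correct(eps, cfg.baseline, cfg.cue_duration)


def preprocess_recordings(recordings: list[RawRecording],
                          calibration: RawRecording,
                          mapping: dict[str, str],
                          config: PreprocessConfig | None = None) -> EpochSet:
    """Convenience front end: reject channels on the first recording, fit the
    chain on the calibration minute, process every recording, concatenate,
    and normalize per session."""
    config = config or PreprocessConfig()
    first_kept, _ = reject_channels(recordings[0], config.reject_rules)
    pre = OfflinePreprocessor(config).fit(calibration,
                                          channel_names=first_kept.channel_names)
    sets = [pre.process(r, mapping) for r in recordings]
    merged = sets[0]
    if len(sets) > 1:
        merged = EpochSet(
            epochs=np.concatenate([s.epochs for s in sets]),
            labels=np.concatenate([s.labels for s in sets]),
            tmin=merged.tmin, tmax=merged.tmax, fs=merged.fs,
            channel_names=merged.channel_names,
            session_ids=np.concatenate([s.session_ids for s in sets]),
            baseline_data=np.concatenate([s.baseline_data for s in sets]),
            trial_ids=np.arange(sum(s.n_trials for s in sets)),
            dropped=sum(s.dropped for s in sets),
        )
    return normalize_sessions(merged)


class StreamingPreprocessor:
    """Chunked chain with carried state: filter -> ASR -> CAR.

    Emits cleaned samples at ASR window granularity. Output equals the batch
    chain run without crop/latency compensation, sample for sample.
    """

    def __init__(self, filt: BandpassFilter, asr: ASRModel):
        self.filter = filt
        self.asr_stream = ASRStream(asr)
        self._state = filt.init_state(asr.n_channels)

    @classmethod
    def from_offline(cls, pre: OfflinePreprocessor) -> "StreamingPreprocessor":
        pre._check_fitted()
        return cls(pre.filter_, pre.asr_)

    def process(self, chunk: np.ndarray) -> np.ndarray:
        y, self._state = self.filter.filter_chunk(chunk, self._state)
        cleaned = self.asr_stream.process(y)
        if cleaned.shape[1] == 0:
            return cleaned
        return common_average_reference(cleaned)

    def flush(self) -> np.ndarray:
        cleaned = self.asr_stream.flush()
        if cleaned.shape[1] == 0:
            return cleaned
        return common_average_reference(cleaned)
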