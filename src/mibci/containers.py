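"""Core in-memory containers: continuous recordings and task-locked epochs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Marker", "RawRecording", "EpochSet"]


@dataclass(frozen=True)
class Marker:
    """An event marker: onset in seconds from recording start, plus a label."""

    onset: float
    label: str


@dataclass
class RawRecording:
    """Continuous multichannel EEG in microvolts with event markers.

    data : (n_channels, n_samples) float array, µV
    fs : sampling rate in Hz
    channel_names : one name per data row
    markers : ordered by onset; onsets within [0, duration]
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    markers: list[Marker] = field(default_factory=list)
    session_id: str = "session-0"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.markers = sorted(self.markers, key=lambda m: m.onset)
        dur = self.duration
        for m in self.markers:
            if not 0.0 <= m.onset <= dur:
                raise ValueError(f"marker {m.label!r} at {m.onset}s outside [0, {dur}]s")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None

    def copy_with(self, **kw) -> "RawRecording":
        out = dict(
            data=self.data.copy(), fs=self.fs,
            channel_names=list(self.channel_names),
            markers=list(self.markers), session_id=self.session_id,
        )
        out.update(kw)
        return RawRecording(**out)


@dataclass
class EpochSet:
    """Task-locked trials: (n_trials, n_channels, n_samples) in µV.

    ``tmin``/``tmax`` are seconds relative to task onset (half-open window
    [tmin, tmax)). ``baseline_data`` optionally carries the pre-task segment
    each trial needs for baseline correction. ``normalization_stats`` maps
    session id -> (mean, sd) arrays of shape (n_channels,) once
    ``normalize_sessions`` has run.
    """

    epochs: np.ndarray
    labels: np.ndarray          # class name per trial (str array)
    tmin: float
    tmax: float
    fs: float
    channel_names: list[str]
    session_ids: np.ndarray | None = None
    baseline_data: np.ndarray | None = None   # (n_trials, n_channels, n_bl_samples)
    trial_ids: np.ndarray | None = None       # source-trial index per row
    window_offsets: np.ndarray | None = None  # seconds from trial start (windowed sets)
    normalization_stats: dict | None = None
    dropped: int = 0                           # trials dropped during construction

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (trials x channels x samples)")
        if len(self.labels) != self.epochs.shape[0]:
            raise ValueError("labels length must equal trial count")
        if self.tmax <= self.tmin:
            raise ValueError("tmax must exceed tmin")
        if not np.all(np.isfinite(self.epochs)):
            raise ValueError("epochs contain non-finite values")
        if self.session_ids is None:
            self.session_ids = np.array(["session-0"] * len(self.labels))
        else:
            self.session_ids = np.asarray(self.session_ids)
        if self.trial_ids is None:
            self.trial_ids = np.arange(len(self.labels))
        else:
            self.trial_ids = np.asarray(self.trial_ids)

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[2]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels.tolist()))

    def copy_with(self, **kw) -> "EpochSet":
        out = dict(
            epochs=self.epochs.copy(), labels=self.labels.copy(),
            tmin=self.tmin, tmax=self.tmax, fs=self.fs,
            channel_names=list(self.channel_names),
            session_ids=None if self.session_ids is None else self.session_ids.copy(),
            baseline_data=None if self.baseline_data is None else self.baseline_data.copy(),
            trial_ids=None if self.trial_ids is None else self.trial_ids.copy(),
            window_offsets=(None if self.window_offsets is None
                            else self.window_offsets.copy()),
            normalization_stats=self.normalization_stats,
            dropped=self.dropped,
        )
        out.update(kw)
        return EpochSet(**out)
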