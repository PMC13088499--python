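"""Seeded synthetic motor-imagery EEG with the structure the pipeline assumes.

The generator emulates an arrow-cue paradigm recording from a 24-channel
mobile EEG: 1/f background activity, alpha (10 Hz) and beta (20 Hz)
oscillations whose amplitude drops at configured channels during task
intervals (event-related desynchronization), stereotyped eye blinks, muscle
bursts, and 50 Hz line interference. A separate entry point produces the
artifact-free calibration minute that artifact-subspace-reconstruction
fitting requires.

Everything derives from a single integer seed: identical configuration gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .containers import Marker, RawRecording
from .montage import (
    DEFAULT_CHANNELS,
    FRONTAL_REFERENCE,
    TEMPORAL_LEFT,
    TEMPORAL_RIGHT,
    spatial_weights,
)

__all__ = [
    "ParadigmSpec",
    "SimConfig",
    "generate_recording",
    "generate_calibration",
    "band_power",
    "TASK_MARKER_PREFIX",
]

TASK_MARKER_PREFIX = "task:"

ALPHA_HZ = 10.0
BETA_HZ = 20.0
BLINK_AMP_UV = 150.0
BLINK_DURATION_S = 0.3
MUSCLE_DURATION_S = 0.5
MUSCLE_GAIN = 5.0  # x background RMS


def _default_vocab(classes: list[str]) -> dict[str, str]:
    known = {"rest": "circle", "left_mi": "arrow_left", "right_mi": "arrow_right"}
    return {c: known.get(c, f"cue_{c}") for c in classes}


@dataclass
class ParadigmSpec:
    """Arrow-cue paradigm timing: break, then a 1 s cue, then a 3 s task."""

    cue_duration: float = 1.0
    task_duration: float = 3.0
    break_duration: float = 3.0
    class_labels: list[str] = field(default_factory=lambda: ["rest", "left_mi", "right_mi"])
    trials_per_class: int = 20
    marker_vocabulary: dict[str, str] | None = None
    lead_in: float = 15.0  # idle head segment; survives the 10 s offline crop

    def __post_init__(self) -> None:
        for name in ("cue_duration", "task_duration", "break_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if len(self.class_labels) < 2:
            raise ValueError("need at least 2 classes")
        if self.trials_per_class < 1:
            raise ValueError("trials_per_class must be >= 1")
        if self.lead_in < 0:
            raise ValueError("lead_in must be >= 0")
        if self.marker_vocabulary is None:
            self.marker_vocabulary = _default_vocab(self.class_labels)
        missing = set(self.class_labels) - set(self.marker_vocabulary)
        if missing:
            raise ValueError(f"marker_vocabulary missing classes: {sorted(missing)}")

    @property
    def trial_period(self) -> float:
        return self.break_duration + self.cue_duration + self.task_duration

    def cue_to_class(self) -> dict[str, str]:
        """The mapping-file content: cue label -> task class."""
        return {v: k for k, v in self.marker_vocabulary.items()}


# default ERD: contralateral motor channels, alpha+beta attenuation
_DEFAULT_ERD: dict[tuple[str, str], float] = {
    ("left_mi", "C4"): 0.5, ("left_mi", "CP6"): 0.3, ("left_mi", "FC6"): 0.3,
    ("right_mi", "C3"): 0.5, ("right_mi", "CP5"): 0.3, ("right_mi", "FC5"): 0.3,
}


@dataclass
class SimConfig:
    """Signal model for the simulated recording (amplitudes in µV)."""

    n_channels: int = 24
    fs: float = 250.0
    channel_names: list[str] | None = None
    background_exponent: float = 1.0
    background_amp: float = 8.0       # µV RMS of 1/f background
    alpha_amp: float = 10.0           # µV oscillation amplitude
    beta_amp: float = 5.0
    erd_depth: dict[tuple[str, str], float] | None = None
    blink_rate: float = 6.0           # events / min
    muscle_rate: float = 2.0          # events / min
    line_amp: float = 2.0             # µV at 50 Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.channel_names is None:
            self.channel_names = DEFAULT_CHANNELS[: self.n_channels]
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must equal n_channels")
        if self.fs <= 2 * 36.0:
            raise ValueError(
                f"fs={self.fs} Hz cannot represent the beta band; need fs > 72 Hz"
            )
        if self.erd_depth is None:
            self.erd_depth = dict(_DEFAULT_ERD)
        for key, d in self.erd_depth.items():
            if not 0.0 <= d < 1.0:
                raise ValueError(f"erd_depth{key} = {d} outside [0, 1)")
        for name in ("background_amp", "alpha_amp", "beta_amp", "blink_rate",
                     "muscle_rate", "line_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _one_over_f(rng: np.random.Generator, n_channels: int, n: int,
                fs: float, exponent: float, amp_rms: float) -> np.ndarray:
    """Gaussian noise with PSD ∝ 1/f**exponent, scaled to amp_rms µV RMS."""
    if amp_rms == 0:
        return np.zeros((n_channels, n))
    white = rng.standard_normal((n_channels, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.ones_like(f)
    nz = f > 0
    shape[nz] = f[nz] ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n, axis=1)
    rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    return x / rms * amp_rms


def _blink_waveform(fs: float) -> np.ndarray:
    """Smoothed biphasic ~300 ms pulse (positive lobe then negative)."""
    n = max(int(round(BLINK_DURATION_S * fs)), 4)
    t = np.arange(n) / n
    return np.sin(np.pi * t) ** 2 * np.sin(2 * np.pi * t)


def _muscle_burst(rng: np.random.Generator, fs: float, rms: float) -> np.ndarray:
    """~500 ms burst of >30 Hz band-limited noise at the given RMS."""
    n = max(int(round(MUSCLE_DURATION_S * fs)), 8)
    x = rng.standard_normal(n)
    sos = sps.butter(4, 30.0, btype="highpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, x)
    x *= np.hanning(n)
    cur = np.sqrt(np.mean(x**2))
    return x / cur * rms if cur > 0 else x


def _add_events(data: np.ndarray, rng: np.random.Generator, fs: float,
                rate_per_min: float, waveform_fn, weights: np.ndarray) -> None:
    n = data.shape[1]
    duration_min = n / fs / 60.0
    count = rng.poisson(rate_per_min * duration_min)
    for _ in range(count):
        wf = waveform_fn()
        start = int(rng.integers(0, max(n - len(wf), 1)))
        seg = slice(start, start + len(wf))
        data[:, seg] += np.outer(weights, wf[: n - start])


def _oscillation(rng: np.random.Generator, n_channels: int, n: int, fs: float,
                 freq: float, amp: float, envelopes: np.ndarray) -> np.ndarray:
    """Per-channel sinusoid with random phase, amplitude-modulated by envelopes."""
    if amp == 0:
        return np.zeros((n_channels, n))
    t = np.arange(n) / fs
    phases = rng.uniform(0, 2 * np.pi, size=n_channels)
    carrier = np.sin(2 * np.pi * freq * t[None, :] + phases[:, None])
    return amp * envelopes * carrier


def generate_recording(sim: SimConfig, paradigm: ParadigmSpec,
                       session_id: str = "sim-0") -> RawRecording:
    """Simulate one cue-paradigm recording.

    The marker stream carries a cue-onset marker labelled with the class's
    cue symbol and a task-onset marker (``task:<symbol>``) at cue offset,
    which is where imagery begins. Task onsets are ``trial_period`` seconds
    apart. During each task interval the alpha/beta amplitude at channel
    ``ch`` is multiplied by ``1 - erd_depth[(class, ch)]``.
    """
    rng = np.random.default_rng(sim.seed)
    classes = paradigm.class_labels
    order = np.repeat(np.arange(len(classes)), paradigm.trials_per_class)
    order = rng.permutation(order)

    tail = 2.0
    duration = paradigm.lead_in + len(order) * paradigm.trial_period + tail
    n = int(round(duration * sim.fs))
    nch = sim.n_channels

    markers: list[Marker] = []
    # per-channel amplitude envelope for the oscillatory component
    env = np.ones((nch, n))
    t_cursor = paradigm.lead_in
    ch_index = {name: i for i, name in enumerate(sim.channel_names)}
    for ci in order:
        cls = classes[ci]
        cue_label = paradigm.marker_vocabulary[cls]
        t_cursor += paradigm.break_duration
        cue_t = t_cursor
        task_t = cue_t + paradigm.cue_duration
        markers.append(Marker(cue_t, cue_label))
        markers.append(Marker(task_t, TASK_MARKER_PREFIX + cue_label))
        i0 = int(round(task_t * sim.fs))
        i1 = int(round((task_t + paradigm.task_duration) * sim.fs))
        for (ecls, ech), depth in sim.erd_depth.items():
            if ecls == cls and ech in ch_index:
                env[ch_index[ech], i0:i1] = 1.0 - depth
        t_cursor = task_t + paradigm.task_duration

    data = _one_over_f(rng, nch, n, sim.fs, sim.background_exponent, sim.background_amp)
    data += _oscillation(rng, nch, n, sim.fs, ALPHA_HZ, sim.alpha_amp, env)
    data += _oscillation(rng, nch, n, sim.fs, BETA_HZ, sim.beta_amp, env)

    if sim.line_amp > 0:
        t = np.arange(n) / sim.fs
        phase = rng.uniform(0, 2 * np.pi)
        data += sim.line_amp * np.sin(2 * np.pi * 50.0 * t + phase)[None, :]

    if sim.blink_rate > 0:
        w = spatial_weights(sim.channel_names, FRONTAL_REFERENCE)
        fs = sim.fs
        _add_events(data, rng, fs, sim.blink_rate,
                    lambda: BLINK_AMP_UV * _blink_waveform(fs), w)
    if sim.muscle_rate > 0:
        burst_rms = MUSCLE_GAIN * max(sim.background_amp, 1.0)
        for side in (TEMPORAL_LEFT, TEMPORAL_RIGHT):
            w = spatial_weights(sim.channel_names, side, falloff=0.4)
            _add_events(data, rng, sim.fs, sim.muscle_rate / 2.0,
                        lambda: _muscle_burst(rng, sim.fs, burst_rms), w)

    return RawRecording(data=data, fs=sim.fs, channel_names=list(sim.channel_names),
                        markers=markers, session_id=session_id)


def generate_calibration(sim: SimConfig, duration: float = 60.0,
                         session_id: str = "calib-0") -> RawRecording:
    """Artifact-free resting segment: no blinks/muscle, no markers, no ERD."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(sim.seed)
    n = int(round(duration * sim.fs))
    nch = sim.n_channels
    env = np.ones((nch, n))
    data = _one_over_f(rng, nch, n, sim.fs, sim.background_exponent, sim.background_amp)
    data += _oscillation(rng, nch, n, sim.fs, ALPHA_HZ, sim.alpha_amp, env)
    data += _oscillation(rng, nch, n, sim.fs, BETA_HZ, sim.beta_amp, env)
    if sim.line_amp > 0:
        t = np.arange(n) / sim.fs
        phase = rng.uniform(0, 2 * np.pi)
        data += sim.line_amp * np.sin(2 * np.pi * 50.0 * t + phase)[None, :]
    return RawRecording(data=data, fs=sim.fs, channel_names=list(sim.channel_names),
                        markers=[], session_id=session_id)


def band_power(rec: RawRecording, channel: str, band: tuple[float, float],
               interval: tuple[float, float]) -> float:
    """Integrated spectral power (µV²) of ``channel`` in ``band`` over ``interval``."""
    f_lo, f_hi = band
    t0, t1 = interval
    if not 0 <= t0 < t1 <= rec.duration + 1e-9:
        raise ValueError(f"invalid interval {interval} for {rec.duration:.2f}s recording")
    if not 0 < f_lo < f_hi < rec.fs / 2:
        raise ValueError(f"band {band} outside (0, {rec.fs / 2}) Hz")
    idx = rec.channel_index(channel)
    i0, i1 = int(round(t0 * rec.fs)), int(round(t1 * rec.fs))
    x = rec.data[idx, i0:i1]
    if x.size < 8:
        raise ValueError("interval too short")
    f, psd = sps.periodogram(x, fs=rec.fs, detrend="constant")
    mask = (f >= f_lo) & (f <= f_hi)
    return float(np.trapezoid(psd[mask], f[mask]))
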