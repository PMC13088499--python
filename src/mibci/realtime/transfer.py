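"""Transfer function: classifier probability streams -> game control signals.

A rolling buffer of the last ``buffer_len`` per-class probability vectors is
averaged each tick (a downsampling/smoothing of the high classification
rate). The most probable class wins if its mean clears its threshold,
otherwise the tick is explicitly *neutral*; argmax ties break toward the
lowest class index. The decision then drives up to five control signals:
continuous x/y axes in [-1, 1] and two binary accumulators that fill on
their mapped class, decay otherwise, and fire for one tick on reaching 1.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

__all__ = ["TransferConfig", "TransferState", "ControlFrame",
           "transfer_update", "map_controls", "NEUTRAL"]

NEUTRAL = "neutral"

# action -> effect on the control frame
_AXIS_ACTIONS = {"x-", "x+", "y-", "y+"}
_BINARY_ACTIONS = {"a", "b"}


@dataclass(frozen=True)
class TransferConfig:
    buffer_len: int = 10
    class_thresholds: dict[str, float] = field(
        default_factory=lambda: {"rest": 0.5, "left_mi": 0.5, "right_mi": 0.5})
    # class -> one of: "neutral", "x-", "x+", "y-", "y+", "a", "b"
    mapping: dict[str, str] = field(default_factory=lambda: {
        "rest": "neutral", "left_mi": "x-", "right_mi": "x+"})
    binary_fill_rate: float = 0.25
    binary_decay_rate: float = 0.25

    def __post_init__(self) -> None:
        if self.buffer_len < 1:
            raise ValueError("buffer_len must be >= 1")
        for c, t in self.class_thresholds.items():
            if not 0 < t <= 1:
                raise ValueError(f"threshold for {c!r} must be in (0, 1]")
        for c, action in self.mapping.items():
            if action not in _AXIS_ACTIONS | _BINARY_ACTIONS | {NEUTRAL}:
                raise ValueError(f"unknown control action {action!r} for {c!r}")

    @property
    def classes(self) -> list[str]:
        return list(self.class_thresholds)


@dataclass
class TransferState:
    buffer: deque = None
    fill_a: float = 0.0
    fill_b: float = 0.0

    @classmethod
    def fresh(cls, config: TransferConfig) -> "TransferState":
        return cls(buffer=deque(maxlen=config.buffer_len))


@dataclass(frozen=True)
class ControlFrame:
    x: float
    y: float
    a: int
    b: int
    tick: int

    def as_dict(self) -> dict:
        return {"tick": self.tick, "x": self.x, "y": self.y,
                "a": self.a, "b": self.b}


def transfer_update(state: TransferState, probs: np.ndarray,
                    config: TransferConfig) -> tuple[TransferState, str]:
    """Push one probability vector; return the smoothed decision.

    The decision is a pure function of the buffer content: argmax of the
    buffer mean, if that mean clears the class threshold, else ``neutral``.
    """
    probs = np.asarray(probs, dtype=float)
    classes = config.classes
    if probs.shape != (len(classes),) or np.any(probs < -1e-9):
        raise ValueError("malformed probability vector")
    if abs(probs.sum() - 1.0) > 1e-3:
        raise ValueError(f"probabilities sum to {probs.sum():.4f}, not 1")
    state.buffer.append(probs)
    mean = np.mean(state.buffer, axis=0)
    winner = int(np.argmax(mean))      # ties -> lowest index
    cls = classes[winner]
    if mean[winner] >= config.class_thresholds[cls]:
        return state, cls
    return state, NEUTRAL


def map_controls(decision: str, config: TransferConfig, state: TransferState,
                 tick: int) -> tuple[ControlFrame, TransferState]:
    """Turn a (class or neutral) decision into one control frame.

    Continuous axes follow the decision's mapped direction (neutral
    re-centers). Binary accumulators gain ``binary_fill_rate`` when their
    class is decided and lose ``binary_decay_rate`` otherwise, clamped to
    [0, 1]; on reaching 1 the signal fires for exactly this tick and the
    accumulator resets.
    """
    if decision != NEUTRAL and decision not in config.mapping:
        raise ValueError(f"unmapped class {decision!r}")
    action = config.mapping.get(decision, NEUTRAL)
    x = {"x-": -1.0, "x+": 1.0}.get(action, 0.0)
    y = {"y-": -1.0, "y+": 1.0}.get(action, 0.0)
    fired = {}
    for name in ("a", "b"):
        fill = getattr(state, f"fill_{name}")
        if action == name:
            fill = min(fill + config.binary_fill_rate, 1.0)
        else:
            fill = max(fill - config.binary_decay_rate, 0.0)
        if fill >= 1.0:
            fired[name] = 1
            fill = 0.0
        else:
            fired[name] = 0
        setattr(state, f"fill_{name}", fill)
    return ControlFrame(x=x, y=y, a=fired["a"], b=fired["b"], tick=tick), state
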