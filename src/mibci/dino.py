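"""Closed-loop training-game evaluator (QuickTime jump mechanic).

During each trial a cue names the motor-imagery class to perform. Every
decoder decision tick either fills an on-screen bar (decision matches the
cue) or decays it (mismatch, clamped at zero). Reaching the threshold
within the trial window triggers the jump — a successful online task
completion; otherwise the trial fails and one health point is lost. The
per-class and overall success rates are the online performance measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator

import numpy as np

__all__ = ["QuickTimeSpec", "TrialResult", "SessionReport", "run_trial",
           "run_session", "scripted_decoder"]


@dataclass(frozen=True)
class QuickTimeSpec:
    window: float = 3.0          # seconds to reach the threshold
    threshold: float = 5.0       # bar units
    fill_rate: float = 1.0       # units per matching decision
    decay_rate: float = 0.5      # units per non-matching decision
    tick_interval: float = 0.1   # seconds between decisions

    def __post_init__(self) -> None:
        if min(self.window, self.threshold, self.fill_rate,
               self.decay_rate, self.tick_interval) <= 0:
            raise ValueError("all QuickTime parameters must be > 0")
        if self.threshold < self.fill_rate:
            raise ValueError("threshold must be >= fill_rate")

    @property
    def ticks(self) -> int:
        return int(round(self.window / self.tick_interval))


@dataclass
class TrialResult:
    cue_class: str
    success: bool
    bar_trajectory: list[float]
    ticks_used: int


@dataclass
class SessionReport:
    per_class_successes: dict[str, int]
    per_class_trials: dict[str, int]
    health_start: int
    trial_results: list[TrialResult] = field(default_factory=list)

    @property
    def total_trials(self) -> int:
        return sum(self.per_class_trials.values())

    @property
    def total_successes(self) -> int:
        return sum(self.per_class_successes.values())

    @property
    def overall_success_rate(self) -> float:
        return self.total_successes / self.total_trials

    @property
    def per_class_rates(self) -> dict[str, float]:
        return {c: self.per_class_successes[c] / n
                for c, n in self.per_class_trials.items() if n}

    @property
    def health_remaining(self) -> int:
        return self.health_start - (self.total_trials - self.total_successes)

    def as_dict(self) -> dict:
        return {
            "per_class": {c: {"trials": self.per_class_trials[c],
                              "successes": self.per_class_successes[c],
                              "rate": self.per_class_rates.get(c)}
                          for c in self.per_class_trials},
            "overall_success_rate": self.overall_success_rate,
            "total_trials": self.total_trials,
            "total_successes": self.total_successes,
            "health_remaining": self.health_remaining,
        }


def run_trial(decisions: Iterable[str], cue_class: str,
              spec: QuickTimeSpec = QuickTimeSpec()) -> TrialResult:
    """One QuickTime event: bar starts at 0, +fill on match, -decay on
    mismatch (clamped at 0); success the first tick the bar reaches the
    threshold, at which point the trial ends."""
    bar = 0.0
    trajectory: list[float] = []
    ticks = 0
    got_any = False
    for decision in decisions:
        got_any = True
        ticks += 1
        if ticks > spec.ticks:
            ticks -= 1
            break
        if decision == cue_class:
            bar += spec.fill_rate
        else:
            bar = max(bar - spec.decay_rate, 0.0)
        trajectory.append(bar)
        if bar >= spec.threshold:
            return TrialResult(cue_class, True, trajectory, ticks)
    if not got_any:
        raise ValueError("empty decision stream")
    return TrialResult(cue_class, False, trajectory, ticks)


def scripted_decoder(classes: list[str], accuracy: float,
                     seed: int = 0) -> Callable[[str], Iterator[str]]:
    """Decision source emitting the cued class with probability ``accuracy``
    and a uniformly random other class otherwise."""
    rng = np.random.default_rng(seed)

    def decisions_for(cue: str) -> Iterator[str]:
        others = [c for c in classes if c != cue]
        while True:
            if rng.random() < accuracy or not others:
                yield cue
            else:
                yield others[rng.integers(len(others))]

    return decisions_for


def run_session(decision_source: Callable[[str], Iterator[str]],
                cue_schedule: list[str],
                spec: QuickTimeSpec = QuickTimeSpec(),
                health_start: int = 3) -> SessionReport:
    """Run the cue schedule trial by trial and aggregate success rates.

    ``decision_source(cue_class)`` yields one decision per tick for that
    trial (a scripted decoder or a live pipeline adapter). Deterministic
    for a deterministic source.
    """
    if not cue_schedule:
        raise ValueError("empty cue schedule")
    successes: dict[str, int] = {}
    trials: dict[str, int] = {}
    results = []
    for cue in cue_schedule:
        stream = decision_source(cue)
        bounded = (next(stream) for _ in range(spec.ticks))
        res = run_trial(bounded, cue, spec)
        results.append(res)
        trials[cue] = trials.get(cue, 0) + 1
        successes[cue] = successes.get(cue, 0) + int(res.success)
    for c in trials:
        successes.setdefault(c, 0)
    return SessionReport(per_class_successes=successes,
                         per_class_trials=trials,
                         health_start=health_start,
                         trial_results=results)
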