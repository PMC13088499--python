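"""Stage-latency statistics and the Wolpaw information transfer rate."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ITRQuery", "compute_itr", "itr_bits_per_selection",
           "latency_summary", "nearest_rank_percentile"]


@dataclass(frozen=True)
class ITRQuery:
    """N classes, accuracy P, T seconds per selection."""

    N: int
    P: float
    T: float

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("need N >= 2 classes")
        if not 0.0 <= self.P <= 1.0:
            raise ValueError("accuracy P must be in [0, 1]")
        if self.T <= 0:
            raise ValueError("selection time T must be > 0")


def itr_bits_per_selection(N: int, P: float) -> float:
    """Wolpaw bits per selection:
    B = log2 N + P log2 P + (1-P) log2((1-P)/(N-1)), with 0 log 0 = 0."""
    b = np.log2(N)
    if P > 0:
        b += P * np.log2(P)
    if P < 1:
        b += (1 - P) * np.log2((1 - P) / (N - 1))
    return float(b)


def compute_itr(q: ITRQuery) -> float:
    """Information transfer rate in bits per minute."""
    return itr_bits_per_selection(q.N, q.P) * 60.0 / q.T


def nearest_rank_percentile(values: np.ndarray, p: float) -> float:
    """Nearest-rank percentile: the ceil(p/100 * n)-th order statistic."""
    values = np.sort(np.asarray(values, dtype=float))
    if values.size == 0:
        raise ValueError("empty sample")
    rank = int(np.ceil(p / 100.0 * values.size))
    return float(values[max(rank, 1) - 1])


def latency_summary(log: list[dict]) -> dict:
    """Per-stage and total delay statistics (ms) from stamped lineages.

    Each log entry carries the four stage stamps (seconds): acquisition_t,
    preprocess_t, classify_t, transfer_t. Reported stages: preprocess
    (preprocess - acquisition), classify, transfer, and total; statistics
    are median / p95 / p99 by the nearest-rank rule.
    """
    if not log:
        raise ValueError("empty latency log")
    deltas = {
        "preprocess": [], "classify": [], "transfer": [], "total": [],
    }
    for rec in log:
        a, p = rec["acquisition_t"], rec["preprocess_t"]
        c, t = rec["classify_t"], rec["transfer_t"]
        deltas["preprocess"].append((p - a) * 1000.0)
        deltas["classify"].append((c - p) * 1000.0)
        deltas["transfer"].append((t - c) * 1000.0)
        deltas["total"].append((t - a) * 1000.0)
    out = {}
    for stage, vals in deltas.items():
        arr = np.asarray(vals)
        out[stage] = {
            "median": nearest_rank_percentile(arr, 50),
            "p95": nearest_rank_percentile(arr, 95),
            "p99": nearest_rank_percentile(arr, 99),
            "n": int(arr.size),
        }
    return out
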