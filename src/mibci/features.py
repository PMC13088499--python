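"""Feature extraction: stacked Morlet time-frequency power + CSP log-variance.

Per 1 s window, two feature families are computed and stacked along the
channel axis of one tensor:

* Morlet wavelet single-trial power (2 cycles per frequency, 8-30 Hz in 2 Hz
  steps, temporal decimation by 3), flattened to channel x frequency planes;
* six common-spatial-pattern log-variance scalars (one-vs-rest, the top and
  bottom generalized eigenvector per class), tiled along the decimated time
  axis so both families share the sequence shape the classifier consumes.

CSP is fitted on training windows only and the decomposition is serialized
with the model so online windows are projected through the identical
filters.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import EpochSet

__all__ = [
    "MorletSpec", "SplitSpec", "FeatureTensor", "CSP",
    "morlet_power", "fit_csp", "csp_features", "sliding_windows",
    "stack_features", "stratified_split", "erds", "extract_features",
]

LOG_VAR_FLOOR = 1e-12


@dataclass(frozen=True)
class MorletSpec:
    freqs: tuple[float, ...] = tuple(float(f) for f in range(8, 31, 2))
    n_cycles: float = 2.0
    decim: int = 3

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.decim < 1:
            raise ValueError("decim must be >= 1")
        if min(self.freqs) <= 0:
            raise ValueError("frequencies must be positive")


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class FeatureTensor:
    """(n_windows, n_feature_channels, n_times) stacked features."""

    data: np.ndarray
    labels: np.ndarray
    trial_ids: np.ndarray
    window_offsets: np.ndarray | None = None
    spec_hash: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("feature tensor must be 3-D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("features contain non-finite values")
        if len(self.labels) != len(self.data):
            raise ValueError("label count must match window count")

    @property
    def n_windows(self) -> int:
        return self.data.shape[0]

    def subset(self, idx: np.ndarray) -> "FeatureTensor":
        return FeatureTensor(
            data=self.data[idx], labels=self.labels[idx],
            trial_ids=self.trial_ids[idx],
            window_offsets=None if self.window_offsets is None
            else self.window_offsets[idx],
            spec_hash=self.spec_hash, meta=dict(self.meta),
        )


def feature_spec_hash(morlet: MorletSpec | None, n_channels: int,
                      n_csp: int, window_samples: int) -> str:
    payload = {
        "freqs": list(morlet.freqs) if morlet else None,
        "n_cycles": morlet.n_cycles if morlet else None,
        "decim": morlet.decim if morlet else None,
        "n_channels": n_channels, "n_csp": n_csp,
        "window_samples": window_samples,
    }
    return hashlib.sha1(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def morlet_power(data: np.ndarray | EpochSet, fs: float | None = None,
                 spec: MorletSpec = MorletSpec()) -> np.ndarray:
    """Single-trial Morlet power, (trials, channels, freqs, times//decim).

    Wavelet support at the lowest frequency (n_cycles / f_min seconds) must
    fit inside the window.
    """
    from mne.time_frequency import tfr_array_morlet

    if isinstance(data, EpochSet):
        fs = data.fs
        data = data.epochs
    if fs is None:
        raise ValueError("fs required for array input")
    data = np.asarray(data, dtype=float)
    n_times = data.shape[-1]
    support = int(np.ceil(spec.n_cycles / min(spec.freqs) * fs))
    if n_times < support:
        raise ValueError(
            f"window of {n_times} samples is shorter than the "
            f"{support}-sample wavelet at {min(spec.freqs)} Hz"
        )
    power = tfr_array_morlet(
        data, sfreq=fs, freqs=np.asarray(spec.freqs),
        n_cycles=spec.n_cycles, output="power", decim=spec.decim,
        zero_mean=True, verbose="error",
    )
    return power


class CSP(BaseEstimator, TransformerMixin):
    """One-vs-rest common spatial patterns with log-variance output.

    For each class the generalized eigenproblem ``Sigma_c w = lambda
    (Sigma_c + Sigma_rest) w`` is solved and the eigenvectors with the
    largest and smallest eigenvalue are kept (2 per class; 6 filters for 3
    classes). Covariances are plain averaged sample covariances — no
    regularization — and outputs are ``log(var(w^T x))``.

    Fitted attributes: ``filters_`` (n_components, n_channels),
    ``eigenvalues_``, ``classes_``.
    """

    def __init__(self, components_per_class: int = 2):
        self.components_per_class = components_per_class

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CSP":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 3:
            raise ValueError("X must be (trials, channels, times)")
        self.classes_ = np.unique(y)
        counts = {c: int(np.sum(y == c)) for c in self.classes_}
        small = [c for c, n in counts.items() if n < 2]
        if small:
            raise ValueError(f"need >= 2 trials per class; too few for {small}")
        n_ch = X.shape[1]
        covs = {}
        for c in self.classes_:
            trials = X[y == c]
            covs[c] = np.einsum("tcs,tds->cd", trials, trials) / (
                trials.shape[0] * trials.shape[2])
        filters, eigvals = [], []
        for c in self.classes_:
            rest = sum(covs[o] for o in self.classes_ if o != c)
            composite = covs[c] + rest
            # solve in the span of the composite covariance: common average
            # referencing leaves one exact null direction, which must not
            # soak up the "minimum variance" filter
            lam, U = sla.eigh(composite)
            keep = lam > max(lam[-1], 0) * 1e-10
            if np.sum(keep) < 2:
                raise ValueError(
                    "composite covariance rank < 2 (e.g. after common "
                    "average referencing of near-constant data); drop a channel"
                )
            P = U[:, keep] / np.sqrt(lam[keep])        # whitener, (n_ch, r)
            w, vw = sla.eigh(P.T @ covs[c] @ P)
            v = P @ vw                                  # back to sensor space
            order = np.argsort(w)
            take = list(order[-1:]) + list(order[:1])
            if self.components_per_class > 2:
                half = self.components_per_class // 2
                take = list(order[::-1][:half]) + list(order[:half])
            for i in take[: self.components_per_class]:
                filters.append(v[:, i])
                eigvals.append(w[i])
        self.filters_ = np.array(filters)           # (n_comp, n_ch)
        self.eigenvalues_ = np.array(eigvals)
        self.n_channels_ = n_ch
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Log-variance of each spatially filtered trial: (n_trials, n_comp)."""
        if not hasattr(self, "filters_"):
            raise RuntimeError("CSP is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_channels_:
            raise ValueError(
                f"X has {X.shape[1]} channels; CSP was fitted on {self.n_channels_}"
            )
        proj = np.einsum("kc,tcs->tks", self.filters_, X)
        var = proj.var(axis=2)
        if np.any(var < LOG_VAR_FLOOR):
            warnings.warn("zero-variance CSP projection floored", stacklevel=2)
            var = np.maximum(var, LOG_VAR_FLOOR)
        return np.log(var)

    def to_dict(self) -> dict:
        return {"filters": self.filters_.tolist(),
                "eigenvalues": self.eigenvalues_.tolist(),
                "classes": self.classes_.tolist(),
                "components_per_class": self.components_per_class}

    @classmethod
    def from_dict(cls, d: dict) -> "CSP":
        obj = cls(components_per_class=d["components_per_class"])
        obj.filters_ = np.array(d["filters"])
        obj.eigenvalues_ = np.array(d["eigenvalues"])
        obj.classes_ = np.array(d["classes"])
        obj.n_channels_ = obj.filters_.shape[1]
        return obj


def fit_csp(epochs: EpochSet | np.ndarray, labels: np.ndarray | None = None,
            components_per_class: int = 2) -> CSP:
    if isinstance(epochs, EpochSet):
        labels = epochs.labels
        epochs = epochs.epochs
    return CSP(components_per_class=components_per_class).fit(epochs, labels)


def csp_features(data: EpochSet | np.ndarray, model: CSP) -> np.ndarray:
    if isinstance(data, EpochSet):
        data = data.epochs
    return model.transform(data)


def sliding_windows(epochs: EpochSet, window: float = 1.0,
                    windows_per_epoch: int = 4) -> EpochSet:
    """Cut each trial into ``windows_per_epoch`` windows of ``window`` s.

    Window starts are evenly spaced from 0 to trial_length - window (stride
    2/3 s for 3 s trials and 4 windows); every window inherits its trial's
    label and source-trial id.
    """
    win = int(round(window * epochs.fs))
    n = epochs.n_samples
    if win > n:
        raise ValueError(f"window of {win} samples exceeds the {n}-sample epoch")
    if windows_per_epoch < 1:
        raise ValueError("windows_per_epoch must be >= 1")
    if windows_per_epoch == 1:
        starts = np.array([0])
    else:
        starts = np.round(np.linspace(0, n - win, windows_per_epoch)).astype(int)
    slabs, labels, trials, offsets, sessions = [], [], [], [], []
    for t in range(epochs.n_trials):
        for s in starts:
            slabs.append(epochs.epochs[t, :, s:s + win])
            labels.append(epochs.labels[t])
            trials.append(epochs.trial_ids[t])
            sessions.append(epochs.session_ids[t])
            offsets.append(s / epochs.fs)
    return EpochSet(
        epochs=np.stack(slabs), labels=np.array(labels),
        tmin=epochs.tmin, tmax=epochs.tmin + window, fs=epochs.fs,
        channel_names=list(epochs.channel_names),
        session_ids=np.array(sessions), trial_ids=np.array(trials),
        window_offsets=np.array(offsets),
        normalization_stats=epochs.normalization_stats,
    )


def stack_features(morlet: np.ndarray | None, csp: np.ndarray | None,
                   labels: np.ndarray, trial_ids: np.ndarray,
                   window_offsets: np.ndarray | None = None,
                   spec_hash: str = "") -> FeatureTensor:
    """Flatten Morlet planes to feature channels and tile CSP scalars in time.

    Either family may be omitted (ablation paths); at least one is required.
    """
    blocks = []
    n_times = None
    if morlet is not None:
        t, c, f, n_times = morlet.shape
        blocks.append(morlet.reshape(t, c * f, n_times))
    if csp is not None:
        if n_times is None:
            n_times = 1
        tiled = np.repeat(csp[:, :, None], n_times, axis=2)
        blocks.append(tiled)
    if not blocks:
        raise ValueError("need Morlet and/or CSP features")
    if len(blocks) == 2 and blocks[0].shape[0] != blocks[1].shape[0]:
        raise ValueError("Morlet and CSP window counts differ")
    data = np.concatenate(blocks, axis=1)
    return FeatureTensor(data=data, labels=labels, trial_ids=trial_ids,
                         window_offsets=window_offsets, spec_hash=spec_hash)


def stratified_split(labels: np.ndarray, trial_ids: np.ndarray,
                     spec: SplitSpec = SplitSpec(),
                     min_per_class: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Stratified 80/20 split at the *source trial* level.

    Returns (train_idx, test_idx) into the window axis. Splitting whole
    trials guarantees windows of one trial never straddle the split; with a
    fixed windows-per-trial count the per-class window fraction equals the
    trial fraction.
    """
    labels = np.asarray(labels)
    trial_ids = np.asarray(trial_ids)
    rng = np.random.default_rng(spec.seed)
    classes, counts = np.unique(labels, return_counts=True)
    low = classes[counts < min_per_class]
    if low.size:
        raise ValueError(f"classes with fewer than {min_per_class} windows: "
                         f"{low.tolist()}")
    if classes.size < 2:
        raise ValueError("need at least two classes to split")
    train_mask = np.zeros(len(labels), dtype=bool)
    for c in classes:
        trials_c = np.unique(trial_ids[labels == c])
        trials_c = rng.permutation(trials_c)
        n_train = int(round(spec.train_fraction * len(trials_c)))
        n_train = min(max(n_train, 1), len(trials_c) - 1)
        chosen = set(trials_c[:n_train].tolist())
        train_mask |= (labels == c) & np.isin(trial_ids, list(chosen))
    return np.flatnonzero(train_mask), np.flatnonzero(~train_mask)


def erds(epochs: EpochSet, baseline: tuple[float, float],
         spec: MorletSpec = MorletSpec()) -> np.ndarray:
    """Relative band-power change map, percent: (channels, freqs, times).

    ``baseline`` is in epoch time (seconds, within [tmin, tmax)); baseline
    power is the trial- and time-averaged power in that interval per
    channel/frequency. Cells with zero baseline power are NaN.
    """
    b0, b1 = baseline
    if not epochs.tmin <= b0 < b1 <= epochs.tmax:
        raise ValueError(f"baseline {baseline} outside epoch "
                         f"[{epochs.tmin}, {epochs.tmax})")
    power = morlet_power(epochs, spec=spec)        # trials x ch x f x t
    times = epochs.tmin + np.arange(power.shape[-1]) * spec.decim / epochs.fs
    sel = (times >= b0) & (times < b1)
    base = power[:, :, :, sel].mean(axis=(0, 3))   # ch x f
    mean_p = power.mean(axis=0)                    # ch x f x t
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * (mean_p - base[:, :, None]) / base[:, :, None]
    out[np.broadcast_to((base == 0)[:, :, None], out.shape)] = np.nan
    return out


def extract_features(windows: EpochSet, csp: CSP | None,
                     morlet: MorletSpec | None = MorletSpec()) -> FeatureTensor:
    """Compute the stacked tensor for a windowed epoch set."""
    mp = morlet_power(windows, spec=morlet) if morlet is not None else None
    cf = csp_features(windows, csp) if csp is not None else None
    h = feature_spec_hash(morlet, windows.n_channels,
                          0 if csp is None else csp.filters_.shape[0],
                          windows.n_samples)
    return stack_features(mp, cf, windows.labels, windows.trial_ids,
                          windows.window_offsets, spec_hash=h)
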