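"""Morlet power, CSP, windowing, stacking, splitting, ERD/ERS maps."""

import numpy as np
import pytest
from scipy import linalg as sla

from mibci.containers import EpochSet
from mibci.features import (CSP, MorletSpec, SplitSpec, erds, fit_csp,
                            morlet_power, sliding_windows, stack_features,
                            stratified_split)

FS = 250.0


def make_epochs(data, labels=None, fs=FS, tmin=0.0):
    n, c, s = data.shape
    return EpochSet(
        epochs=data, labels=np.array(labels if labels is not None else ["x"] * n),
        tmin=tmin, tmax=tmin + s / fs, fs=fs,
        channel_names=[f"ch{i}" for i in range(c)])


def exact_cov_trials(cov, n_trials, n_samples, rng):
    """Trials whose sample covariance is exactly ``cov`` (orthogonal rows)."""
    L = np.linalg.cholesky(cov)
    out = []
    for _ in range(n_trials):
        Q, _ = np.linalg.qr(rng.standard_normal((n_samples, n_samples)))
        Z = Q[: cov.shape[0]].T * np.sqrt(n_samples)  # rows: exact identity cov
        out.append(L @ Z.T)
    return np.stack(out)


class TestMorlet:
    def test_peak_at_signal_frequency(self):
        t = np.arange(750) / FS
        sig = np.sin(2 * np.pi * 10 * t)[None, None, :]
        p = morlet_power(sig, fs=FS)
        freqs = np.array(MorletSpec().freqs)
        mid = p[0, 0, :, 40:80].mean(axis=1)
        assert freqs[np.argmax(mid)] == 10.0

    def test_zero_in_zero_out(self):
        p = morlet_power(np.zeros((1, 2, 750)), fs=FS)
        assert np.allclose(p, 0.0)

    def test_decimation_length(self):
        p = morlet_power(np.random.default_rng(0).standard_normal((2, 3, 750)),
                         fs=FS)
        assert p.shape == (2, 3, 12, 250)

    def test_sign_flip_invariance_and_quadratic_scaling(self, rng):
        x = rng.standard_normal((1, 2, 500))
        p1 = morlet_power(x, fs=FS)
        assert np.allclose(morlet_power(-x, fs=FS), p1)
        assert np.allclose(morlet_power(2 * x, fs=FS), 4 * p1, rtol=1e-10)

    def test_window_too_short(self):
        with pytest.raises(ValueError, match="shorter"):
            morlet_power(np.zeros((1, 1, 30)), fs=FS)


class TestCSP:
    def test_axis_aligned_two_channel(self, rng):
        """Class covariances diag(2,1) vs diag(1,2): eigenvalues 2/3 and 1/3,
        filters along the coordinate axes."""
        Xa = exact_cov_trials(np.diag([2.0, 1.0]), 4, 64, rng)
        Xb = exact_cov_trials(np.diag([1.0, 2.0]), 4, 64, rng)
        X = np.concatenate([Xa, Xb])
        y = np.array(["a"] * 4 + ["b"] * 4)
        csp = CSP().fit(X, y)
        assert np.allclose(sorted(csp.eigenvalues_), [1 / 3, 1 / 3, 2 / 3, 2 / 3],
                           atol=1e-10)
        for w in csp.filters_:
            w = np.abs(w / np.linalg.norm(w))
            assert np.allclose(sorted(w), [0.0, 1.0], atol=1e-8)

    def test_identical_covariances_no_discrimination(self, rng):
        X = exact_cov_trials(np.eye(3), 8, 81, rng)
        y = np.array(["a", "b"] * 4)
        csp = CSP().fit(X, y)
        assert np.allclose(csp.eigenvalues_, 0.5, atol=1e-10)

    def test_matches_generalized_eig_oracle(self, rng):
        """Brute-force generalized eigenvectors on random SPD pairs."""
        for _ in range(5):
            A0 = rng.standard_normal((5, 5))
            B0 = rng.standard_normal((5, 5))
            S1 = A0 @ A0.T + 0.2 * np.eye(5)
            S2 = B0 @ B0.T + 0.2 * np.eye(5)
            X = np.concatenate([exact_cov_trials(S1, 3, 125, rng),
                                exact_cov_trials(S2, 3, 125, rng)])
            y = np.array(["a"] * 3 + ["b"] * 3)
            csp = CSP().fit(X, y)
            w_ref, v_ref = sla.eigh(S1, S1 + S2)
            for want in (v_ref[:, -1], v_ref[:, 0]):
                want = want / np.linalg.norm(want)
                dots = [abs(np.dot(want, f / np.linalg.norm(f)))
                        for f in csp.filters_]
                assert max(dots) > 1 - 1e-8

    def test_too_few_trials(self, rng):
        X = rng.standard_normal((3, 2, 50))
        with pytest.raises(ValueError, match="2 trials"):
            CSP().fit(X, np.array(["a", "a", "b"]))

    def test_log_variance_scaling(self, rng):
        X = exact_cov_trials(np.eye(3), 6, 81, rng)
        y = np.array(["a", "b"] * 3)
        csp = CSP().fit(X, y)
        f1 = csp.transform(X)
        f2 = csp.transform(2 * X)
        assert np.allclose(f2 - f1, np.log(4.0))

    def test_white_noise_features_near_log_sigma2(self, rng):
        sigma2 = 2.5
        X = exact_cov_trials(sigma2 * np.eye(4), 6, 100, rng)
        y = np.array(["a", "b", "a", "b", "a", "b"])
        csp = CSP().fit(X, y)
        feats = csp.transform(X)
        # filters are composite-covariance-orthonormal: w' (2*sigma2 I) w = 1
        # (log-variance uses the mean-removed variance, hence ~1/T slack)
        assert np.allclose(np.exp(feats), 0.5, rtol=0.15)

    def test_channel_mismatch(self, rng):
        X = exact_cov_trials(np.eye(3), 4, 60, rng)
        csp = CSP().fit(X, np.array(["a", "b", "a", "b"]))
        with pytest.raises(ValueError, match="channels"):
            csp.transform(rng.standard_normal((2, 4, 60)))

    def test_serialization_roundtrip(self, rng):
        X = exact_cov_trials(np.eye(3), 4, 60, rng)
        csp = CSP().fit(X, np.array(["a", "b", "a", "b"]))
        again = CSP.from_dict(csp.to_dict())
        assert np.allclose(again.transform(X), csp.transform(X))


class TestWindowing:
    @pytest.mark.parametrize("n_trials,expected", [(190, 760), (720, 2880)])
    def test_window_counts(self, n_trials, expected):
        eps = make_epochs(np.zeros((n_trials, 2, 750)))
        wins = sliding_windows(eps)
        assert wins.n_trials == expected

    def test_stride_two_thirds_second(self):
        eps = make_epochs(np.zeros((1, 2, 750)))
        wins = sliding_windows(eps)
        assert np.allclose(np.diff(wins.window_offsets), 2 / 3, atol=1 / FS)

    def test_single_window_degenerate(self):
        eps = make_epochs(np.zeros((2, 2, 250)))
        wins = sliding_windows(eps, window=1.0, windows_per_epoch=1)
        assert wins.n_trials == 2
        assert np.all(wins.window_offsets == 0.0)

    def test_window_longer_than_epoch(self):
        eps = make_epochs(np.zeros((1, 2, 100)))
        with pytest.raises(ValueError, match="exceeds"):
            sliding_windows(eps, window=1.0)

    def test_labels_and_trials_inherited(self):
        eps = make_epochs(np.zeros((2, 2, 750)), labels=["l", "r"])
        wins = sliding_windows(eps)
        assert list(wins.labels) == ["l"] * 4 + ["r"] * 4
        assert list(wins.trial_ids) == [0] * 4 + [1] * 4


class TestStacking:
    def test_feature_channel_arithmetic(self, rng):
        morlet = rng.random((10, 24, 12, 84))
        csp = rng.standard_normal((10, 6))
        labels = np.array(["x"] * 10)
        ft = stack_features(morlet, csp, labels, np.arange(10))
        assert ft.data.shape == (10, 294, 84)
        # CSP scalars tiled along time
        assert np.allclose(ft.data[:, 288:, 0], csp)
        assert np.allclose(ft.data[:, 288:, -1], csp)

    def test_ablation_paths(self, rng):
        morlet = rng.random((4, 24, 12, 84))
        csp = rng.standard_normal((4, 6))
        labels = np.array(["x"] * 4)
        assert stack_features(morlet, None, labels, np.arange(4)).data.shape[1] == 288
        assert stack_features(None, csp, labels, np.arange(4)).data.shape[1] == 6

    def test_count_mismatch(self, rng):
        with pytest.raises(ValueError, match="differ"):
            stack_features(rng.random((4, 2, 3, 8)), rng.random((5, 6)),
                           np.array(["x"] * 4), np.arange(4))


class TestSplit:
    def test_eighty_twenty_counts(self):
        labels = np.repeat(["a", "b", "c"], 252)          # 63 trials x 4 windows
        trials = np.repeat(np.arange(189), 4)
        tr, te = stratified_split(labels, trials, SplitSpec(seed=1))
        assert len(tr) + len(te) == 756
        for c in "abc":
            n_tr = np.sum(labels[tr] == c)
            assert abs(n_tr - round(0.8 * 252)) <= 4   # whole-trial granularity

    def test_deterministic(self):
        labels = np.repeat(["a", "b"], 40)
        trials = np.repeat(np.arange(20), 4)
        s1 = stratified_split(labels, trials, SplitSpec(seed=7))
        s2 = stratified_split(labels, trials, SplitSpec(seed=7))
        assert np.array_equal(s1[0], s2[0])

    def test_no_trial_leakage(self):
        labels = np.repeat(["a", "b", "c"], 40)
        trials = np.repeat(np.arange(30), 4)
        tr, te = stratified_split(labels, trials)
        assert not set(trials[tr]) & set(trials[te])

    def test_single_class_errors(self):
        labels = np.array(["a"] * 40)
        with pytest.raises(ValueError):
            stratified_split(labels, np.repeat(np.arange(10), 4))

    def test_tiny_class_named(self):
        labels = np.array(["a"] * 40 + ["tiny"] * 2)
        trials = np.concatenate([np.repeat(np.arange(10), 4), [10, 10]])
        with pytest.raises(ValueError, match="tiny"):
            stratified_split(labels, trials)


class TestERDS:
    def test_synthetic_depth_recovered(self):
        """Amplitude attenuation 0.5 during the task -> about -75% alpha power
        relative to the pre-task baseline."""
        t = np.arange(int(5 * FS)) / FS
        env = np.where(t >= 2.0, 0.5, 1.0)
        data = (env * np.sin(2 * np.pi * 10 * t))[None, None, :]
        eps = make_epochs(np.repeat(data, 3, axis=0), labels=list("xxx"), tmin=-2.0)
        m = erds(eps, baseline=(-1.8, -0.2))
        freqs = np.array(MorletSpec().freqs)
        fi = int(np.argmin(np.abs(freqs - 10)))
        times = eps.tmin + np.arange(m.shape[-1]) * 3 / FS
        task = m[0, fi, (times > 0.5) & (times < 2.5)]
        assert np.mean(task) == pytest.approx(-75.0, abs=5.0)

    def test_no_modulation_near_zero(self, rng):
        data = rng.standard_normal((6, 2, int(4 * FS)))
        eps = make_epochs(data, labels=list("xxxxxx"), tmin=-2.0)
        m = erds(eps, baseline=(-1.8, -0.2))
        times = eps.tmin + np.arange(m.shape[-1]) * 3 / FS
        task = m[:, :, (times > 0.2) & (times < 1.8)]
        assert abs(np.nanmean(task)) < 15.0

    def test_baseline_outside_epoch(self):
        eps = make_epochs(np.zeros((1, 1, 750)))
        with pytest.raises(ValueError):
            erds(eps, baseline=(-1.0, 0.0))
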