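"""Point-biserial selection, shrinkage LDA, decoding, discriminability."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

import erpspeller as es
from erpspeller import classification as clf
from erpspeller import preprocessing as prep


def make_epochs(data, labels, fs=100.0):
    n, n_ch, n_t = data.shape
    times = (np.round(-170 * fs / 1000) + np.arange(n_t)) * 1000 / fs
    return prep.EpochSet(
        data=np.asarray(data, dtype=float),
        times_ms=times,
        channels=es.CHANNELS_64[:n_ch],
        labels=np.asarray(labels, dtype=bool),
        kept=np.ones(n, dtype=bool),
        reasons=np.array([""] * n, dtype=object),
        meta=pd.DataFrame({"index": range(n), "level": 1, "phase": "core"}),
        fs_hz=fs,
    )


class TestPointBiserial:
    def test_value_equals_label_gives_unit_correlation(self):
        y = np.array([0, 1, 0, 1, 1, 0])
        x = y.astype(float)[:, None]
        assert clf.point_biserial(x, y)[0] == pytest.approx(1.0)

    def test_constant_signal_gives_zero(self):
        x = np.full((8, 3), 2.5)
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        assert (clf.point_biserial(x, y) == 0).all()

    def test_hand_worked_case_matches_scipy_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([0, 0, 0, 1, 1, 1])
        expected = scipy.stats.pointbiserialr(y, x).correlation
        got = clf.point_biserial(x[:, None], y)[0]
        assert got == pytest.approx(expected, rel=1e-12)

    def test_bounded_by_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(40, 6, 10))
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]  # ensure both classes
        r = clf.point_biserial(x, y)
        assert r.shape == (6, 10)
        assert np.all(np.abs(r) <= 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            clf.point_biserial(np.ones((4, 2)), np.ones(4))


class TestSelectTemporalWindows:
    def test_two_bumps_recovered(self):
        times = np.arange(-170, 671, 10.0)
        r = np.zeros((3, len(times)))
        r[0] = 0.6 * np.exp(-((times - 180) ** 2) / (2 * 25**2))
        r[1] = -0.5 * np.exp(-((times - 400) ** 2) / (2 * 25**2))
        wins = clf.select_temporal_windows(r, times, k=2, width_ms=40,
                                           min_separation_ms=50)
        centers = [(lo + hi) / 2 for lo, hi in wins]
        assert abs(centers[0] - 180) <= 20 and abs(centers[1] - 400) <= 20

    def test_flat_map_warns_and_returns_nothing(self):
        times = np.arange(-170, 671, 10.0)
        with pytest.warns(UserWarning, match="peaks"):
            wins = clf.select_temporal_windows(np.zeros((2, len(times))),
                                               times, k=3)
        assert wins == ()

    def test_windows_respect_separation_and_sorting(self):
        rng = np.random.default_rng(3)
        times = np.arange(-170, 671, 10.0)
        r = rng.uniform(0.1, 1.0, size=(1, len(times)))
        wins = clf.select_temporal_windows(r, times, k=7, width_ms=40,
                                           min_separation_ms=50)
        centers = np.array([(lo + hi) / 2 for lo, hi in wins])
        assert (np.diff(centers) >= 40).all()  # implied by 50 ms separation
        assert all(w[0] < w[1] for w in wins)
        assert all(times[0] <= lo and hi <= times[-1] for lo, hi in wins)


class TestBuildFeatures:
    def test_whole_epoch_window_gives_channel_means(self):
        data = np.arange(2 * 3 * 85).reshape(2, 3, 85).astype(float)
        epochs = make_epochs(data, [0, 1])
        spec = clf.FeatureSpec(
            channels=epochs.channels,
            windows=((epochs.times_ms[0], epochs.times_ms[-1]),),
        )
        X, y = clf.build_features(epochs, spec)
        assert X.shape == (2, 3)
        assert np.allclose(X, data.mean(axis=2))
        assert (y == [0, 1]).all()

    def test_constant_epoch_constant_features(self):
        epochs = make_epochs(np.full((1, 4, 85), 3.3), [1])
        spec = clf.FeatureSpec(
            channels=epochs.channels,
            windows=((0.0, 100.0), (200.0, 300.0)),
        )
        X, _ = clf.build_features(epochs, spec)
        assert np.allclose(X, 3.3) and X.shape == (1, 8)

    def test_dimensionality_is_channels_times_windows(self):
        epochs = make_epochs(np.zeros((3, 5, 85)), [0, 1, 0])
        spec = clf.FeatureSpec(
            channels=epochs.channels[:4],
            windows=((0, 40), (100, 140), (300, 340)),
        )
        assert spec.dimensionality == 12
        X, _ = clf.build_features(epochs, spec)
        assert X.shape == (3, 12)

    def test_window_outside_epoch_rejected(self):
        epochs = make_epochs(np.zeros((2, 2, 85)), [0, 1])
        spec = clf.FeatureSpec(channels=epochs.channels,
                               windows=((900.0, 950.0),))
        with pytest.raises(ValueError, match="outside"):
            clf.build_features(epochs, spec)


def classical_lda_oracle(X, y):
    """Direct-solve classical LDA weights (independent of the package)."""
    X0, X1 = X[y == 0], X[y == 1]
    mu0, mu1 = X0.mean(0), X1.mean(0)
    Z = np.concatenate([X0 - mu0, X1 - mu1])
    S = Z.T @ Z / (len(Z) - 1)
    return np.linalg.solve(S, mu1 - mu0)


def gaussian_problem(rng, n_per_class, d, sep=1.0):
    A = rng.normal(size=(d, d)) / np.sqrt(d)
    cov_half = A + 0.5 * np.eye(d)
    mu = rng.normal(size=d) * sep / np.sqrt(d)
    X0 = rng.normal(size=(n_per_class, d)) @ cov_half
    X1 = rng.normal(size=(n_per_class, d)) @ cov_half + mu
    X = np.concatenate([X0, X1])
    y = np.repeat([0, 1], n_per_class)
    return X, y


class TestShrinkageLDA:
    def test_gamma_zero_matches_classical_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            X, y = gaussian_problem(rng, 60, 8)
            model = clf.train_shrinkage_lda(X, y, gamma=0.0)
            assert np.allclose(model.weights, classical_lda_oracle(X, y),
                               rtol=1e-8, atol=1e-10)

    def test_gamma_zero_direction_matches_sklearn(self):
        rng = np.random.default_rng(2)
        X, y = gaussian_problem(rng, 80, 6)
        model = clf.train_shrinkage_lda(X, y, gamma=0.0)
        sk = LinearDiscriminantAnalysis(solver="lsqr").fit(X, y)
        w_sk = sk.coef_.ravel()
        cos = w_sk @ model.weights / (
            np.linalg.norm(w_sk) * np.linalg.norm(model.weights)
        )
        assert cos == pytest.approx(1.0, abs=1e-8)

    def test_gamma_one_closed_form(self):
        rng = np.random.default_rng(3)
        X, y = gaussian_problem(rng, 30, 10)
        model = clf.train_shrinkage_lda(X, y, gamma=1.0)
        mu0, mu1 = X[y == 0].mean(0), X[y == 1].mean(0)
        Z = np.concatenate([X[y == 0] - mu0, X[y == 1] - mu1])
        nu = np.trace(Z.T @ Z / (len(Z) - 1)) / X.shape[1]
        assert np.allclose(model.weights, (mu1 - mu0) / nu, rtol=1e-10)

    def test_auto_gamma_in_unit_interval_high_dim(self):
        rng = np.random.default_rng(4)
        X, y = gaussian_problem(rng, 100, 385, sep=2.0)
        model = clf.train_shrinkage_lda(X, y, gamma="auto")
        assert 0.0 < model.gamma < 1.0

    def test_shrinkage_beats_classical_in_high_dim(self):
        """d = 385, n = 100 per class: mean held-out accuracy of auto-gamma
        shrinkage LDA must beat the near-singular classical solution over
        20 repetitions — the reason shrinkage is used at all."""
        rng = np.random.default_rng(5)
        wins_auto, wins_plain = [], []
        for _ in range(20):
            X, y = gaussian_problem(rng, 100, 385, sep=2.0)
            Xt, yt = gaussian_problem(rng, 200, 385, sep=2.0)
            # held-out draw shares no samples; same distribution family
            auto = clf.ShrinkageLDA("auto").fit(X, y)
            plain = clf.ShrinkageLDA(0.0).fit(X, y)
            wins_auto.append((auto.predict(Xt) == yt).mean())
            wins_plain.append((plain.predict(Xt) == yt).mean())
        assert np.mean(wins_auto) > np.mean(wins_plain)

    def test_bias_centers_threshold_between_means(self):
        rng = np.random.default_rng(6)
        X, y = gaussian_problem(rng, 50, 5)
        model = clf.train_shrinkage_lda(X, y, gamma=0.2)
        mu0, mu1 = X[y == 0].mean(0), X[y == 1].mean(0)
        assert clf.score(model, (mu0 + mu1) / 2)[0] == pytest.approx(0.0,
                                                                     abs=1e-9)
        assert clf.score(model, mu1)[0] > 0 > clf.score(model, mu0)[0]

    def test_batch_scoring_matches_elementwise(self):
        rng = np.random.default_rng(7)
        X, y = gaussian_problem(rng, 30, 4)
        model = clf.train_shrinkage_lda(X, y)
        batch = clf.score(model, X)
        single = np.array([clf.score(model, x)[0] for x in X])
        assert np.allclose(batch, single)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="gamma"):
            clf.ShrinkageLDA(1.5)
        with pytest.raises(ValueError, match="two classes"):
            clf.ShrinkageLDA().fit(np.zeros((4, 2)), np.zeros(4))
        with pytest.raises(ValueError, match="at least 2"):
            clf.ShrinkageLDA().fit(np.zeros((3, 2)), np.array([0, 1, 1]))
        rng = np.random.default_rng(8)
        X, y = gaussian_problem(rng, 10, 3)
        model = clf.train_shrinkage_lda(X, y)
        with pytest.raises(ValueError, match="feature length"):
            clf.score(model, np.zeros((2, 7)))


class TestDecodeTrial:
    def test_perfect_outputs_decode_every_symbol(self, matrix_layout,
                                                 hex_layout):
        for layout in (matrix_layout, hex_layout):
            sch = es.generate_trial_schedule(layout, "K", seed=2)
            frame = sch.to_frame()
            outputs = frame["is_target"].to_numpy(dtype=float)
            for n in (1, 5, 10):
                assert clf.decode_trial(outputs, sch, n) == "K"

    def test_hex_empty_disc_yields_backdoor(self, hex_layout):
        sch = es.generate_trial_schedule(hex_layout, "A", seed=3)
        frame = sch.to_frame()
        outputs = np.zeros(len(frame))
        # level 1: correct group wins; level 2: empty disc (id 5) wins
        lvl1 = (frame["level"] == 1) & frame["is_target"]
        lvl2 = (frame["level"] == 2) & (frame["element_id"] == 5)
        outputs[lvl1.to_numpy()] = 1.0
        outputs[lvl2.to_numpy()] = 1.0
        assert clf.decode_trial(outputs, sch, 10) == es.BACKDOOR

    def test_all_zero_outputs_tie_break_to_lowest_ids(self, matrix_layout):
        sch = es.generate_trial_schedule(matrix_layout, "B", seed=4)
        outputs = np.zeros(sch.n_events)
        sym = clf.decode_trial(outputs, sch, 10)
        assert sym == es.decode_selection(matrix_layout, (0, 6))

    def test_out_of_range_inputs_rejected(self, matrix_layout):
        sch = es.generate_trial_schedule(matrix_layout, "B", seed=4)
        with pytest.raises(ValueError, match="n_sequences"):
            clf.decode_trial(np.zeros(sch.n_events), sch, 11)
        with pytest.raises(ValueError, match="length"):
            clf.decode_trial(np.zeros(10), sch, 5)

    def test_perfect_curve_is_flat_one(self, matrix_layout):
        trials = []
        for seed in (1, 2, 3):
            sch = es.generate_trial_schedule(matrix_layout, "F", seed=seed)
            outputs = sch.to_frame()["is_target"].to_numpy(dtype=float)
            trials.append(("F", outputs, sch))
        result = clf.accuracy_curve(trials)
        assert (result.accuracy_curve == 1.0).all()
        assert len(result.accuracy_curve) == 10


class TestDiscriminabilityMaps:
    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(9)
        data = rng.normal(size=(160, 8, 40))
        labels = np.repeat([0, 1], 80)
        rng.shuffle(labels)
        epochs = make_epochs(data, labels)
        errs = clf.electrode_errors(epochs, gamma="auto", n_folds=4)
        assert errs.between(0.35, 0.65).all()

    def test_informative_channel_has_lowest_error(self):
        rng = np.random.default_rng(10)
        data = rng.normal(size=(200, 6, 40))
        labels = np.repeat([0, 1], 100)
        t = np.arange(40)
        bump = np.exp(-((t - 25) ** 2) / 18.0)
        data[labels == 1, 2, :] += 2.0 * bump
        epochs = make_epochs(data, labels)
        errs = clf.electrode_errors(epochs, n_folds=4)
        assert errs.idxmin() == epochs.channels[2]

    def test_window_errors_dip_at_signal_latency(self):
        rng = np.random.default_rng(11)
        fs = 100.0
        data = rng.normal(size=(200, 4, 85))
        labels = np.repeat([0, 1], 100)
        times = (np.round(-170 * fs / 1000) + np.arange(85)) * 1000 / fs
        bump = np.exp(-((times - 400.0) ** 2) / (2 * 40.0**2))
        data[labels == 1] += 1.5 * bump[None, None, :]
        epochs = make_epochs(data, labels)
        table = clf.window_errors(epochs, n_folds=4)
        best = table.loc[table["error"].idxmin(), "center_ms"]
        assert 300.0 <= best <= 500.0
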