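"""Preprocessing, decoders, decision-variable extraction and generalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from postbias import neural
from postbias.neural import (
    EpochSet,
    SlidingFeatures,
    decode_dv,
    dv_trend,
    highpass_response,
    peak_decodability,
    preprocess,
    sensor_contributions,
    sliding_features,
    temporal_generalization,
    train_decoders,
    unsign,
)
from postbias.synth import EpochGroundTruth, simulate_epochs


def _epochs(data, rate=100.0, t0=0.0, labels=None):
    n, c, s = data.shape
    return EpochSet(
        data=data,
        sampling_rate=rate,
        times=t0 + 1000.0 / rate * np.arange(s),
        labels=labels if labels is not None else pd.DataFrame(index=range(n)),
        channels=[f"ch{i}" for i in range(c)],
    )


class TestPreprocess:
    def test_600hz_segment_becomes_821_samples_at_100hz(self):
        # -200..+8000 ms at 600 Hz = 4921 samples -> 821 at 100 Hz
        raw = _epochs(np.random.default_rng(0).normal(size=(2, 3, 4921)), rate=600.0, t0=-200.0)
        out = preprocess(raw)
        assert out.data.shape == (2, 3, 821)
        assert out.sampling_rate == 100.0
        assert out.times[0] == pytest.approx(-200.0)

    def test_dc_channel_removed_by_highpass(self):
        data = np.zeros((1, 2, 1200))
        data[0, 0] = 5.0  # constant channel
        data[0, 1] = np.random.default_rng(1).normal(size=1200)
        out = preprocess(_epochs(data), target_rate=100.0)
        assert np.abs(out.data[0, 0]).max() < 1e-6

    def test_filter_attenuation_matches_designed_response(self):
        # long sinusoids: stop-band (0.1 Hz) attenuated at least as much as
        # designed, pass-band (10 Hz) within ripple of unity
        fs, dur = 100.0, 120.0
        t = np.arange(int(fs * dur)) / fs
        for freq, band in ((0.1, "stop"), (10.0, "pass")):
            x = np.sin(2 * np.pi * freq * t)[None, None, :]
            out = preprocess(_epochs(x), target_rate=fs)
            mid = slice(int(20 * fs), int(100 * fs))  # avoid edge transients
            gain = np.sqrt(np.mean(out.data[0, 0, mid] ** 2) / np.mean(x[0, 0, mid] ** 2))
            designed = highpass_response(freq, 0.5, fs)
            if band == "stop":
                assert gain <= designed * 1.5 and gain < 0.01
            else:
                assert gain == pytest.approx(1.0, abs=0.01)

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError):
            preprocess(_epochs(np.zeros((1, 2, 4))))

    def test_realignment_shifts_time_axis(self):
        raw = _epochs(np.zeros((1, 1, 500)), rate=100.0, t0=-200.0)
        out = preprocess(raw, realign_to_ms=1000.0, alignment="post_evidence")
        assert out.times[0] == pytest.approx(-1200.0)
        assert out.alignment == "post_evidence"


class TestSlidingFeatures:
    def test_constant_data_standardizes_to_zero(self):
        f = sliding_features(_epochs(np.full((5, 3, 50), 2.5)), standardize=True)
        assert np.allclose(f.X, 0.0)

    def test_windowed_mean_matches_boxcar_on_toy_array(self):
        data = np.arange(20, dtype=float)[None, None, :]
        f = sliding_features(_epochs(data), window_ms=50.0, step_ms=10.0)
        # nominal timepoint 90 ms: samples in (40, 90] -> indices 5..9
        k = int(np.flatnonzero(f.times_ms == 90.0)[0])
        assert f.X[k, 0, 0] == pytest.approx(np.mean(data[0, 0, 5:10]))

    def test_zscore_contract_mean_zero_sd_one(self):
        data = np.random.default_rng(3).normal(size=(40, 4, 60))
        f = sliding_features(_epochs(data), standardize=True)
        assert np.abs(f.X.mean(axis=1)).max() < 1e-10
        assert np.abs(f.X.std(axis=1) - 1.0).max() < 1e-10

    def test_nonpositive_step_rejected(self):
        with pytest.raises(ValueError):
            sliding_features(_epochs(np.zeros((1, 1, 50))), step_ms=0.0)


def _blobs(n=60, c=10, sep=6.0, seed=0, T=3):
    rng = np.random.default_rng(seed)
    y = np.repeat(["left", "right"], n // 2)
    centre = rng.normal(size=c)
    X = np.empty((T, n, c))
    for t in range(T):
        X[t] = rng.normal(size=(n, c)) + np.where(y == "right", 1.0, -1.0)[:, None] * sep * centre / np.linalg.norm(centre)
    return SlidingFeatures(X=X, times_ms=10.0 * np.arange(T)), y


class TestDecoders:
    def test_separable_blobs_perfect_heldout_accuracy(self):
        feats, y = _blobs(sep=8.0)
        ens = train_decoders(feats, y, scheme="loo")
        dv = decode_dv(ens, feats)
        signs = np.where(np.asarray(y) == "right", 1, -1)
        assert np.mean(np.sign(dv.dv.mean(axis=1)) == signs) == 1.0

    def test_permuted_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(7)
        feats, y = _blobs(n=200, sep=5.0, T=1)
        y_perm = rng.permutation(np.asarray(y))
        ens = train_decoders(feats, y_perm, scheme="loo")
        dv = decode_dv(ens, feats)
        signs = np.where(y_perm == "right", 1, -1)
        acc = np.mean(np.sign(dv.dv[:, 0]) == signs)
        assert abs(acc - 0.5) <= 3 * np.sqrt(0.25 / 200)

    def test_default_regularization_constant_is_one(self):
        feats, y = _blobs()
        ens = train_decoders(feats, y, scheme="all")
        assert ens.C == 1.0
        assert neural.DEFAULT_C == 1.0

    def test_single_class_labels_rejected(self):
        feats, _ = _blobs(n=10)
        with pytest.raises(ValueError):
            train_decoders(feats, ["left"] * 10, scheme="loo")


class TestDecisionVariable:
    def test_feature_on_hyperplane_scores_zero(self):
        feats, y = _blobs(sep=4.0, T=1)
        ens = train_decoders(feats, y, scheme="all")
        w, b = ens.weights[0], ens.intercepts[0]
        mu = feats.X.mean(axis=(0, 1))
        sd = feats.X.std(axis=(0, 1))
        # construct a standardized point on the hyperplane, map it back
        x_std = -b * w / np.dot(w, w)
        probe = SlidingFeatures(X=(x_std * sd + mu)[None, None, :], times_ms=feats.times_ms[:1])
        ens1 = neural.DecoderEnsemble(ens.weights[:1], ens.intercepts[:1], "all",
                                      feats.times_ms[:1], ens.C, ens.n_train)
        dv = decode_dv(ens1, probe, train_post=feats)
        assert dv.dv[0, 0] == pytest.approx(0.0, abs=1e-10)

    def test_doubling_pattern_amplitude_doubles_dv(self, session_table):
        # linearity of a frozen rule: same ensemble and normalization,
        # scaled input pattern -> scaled DV
        trials = session_table.iloc[:40].reset_index(drop=True)
        kw = dict(n_channels=16, n_samples=121, post_onset_ms=300, window_ms=400,
                  noise_scale=0.0, slope_jitter=0.0, spatial_corr_length=3.0)
        t1 = EpochGroundTruth(**kw)
        ep1, t1 = simulate_epochs(trials, t1, seed=5)
        t2 = EpochGroundTruth(
            **{**kw, "pre_amplitude": 2.0, "intercept0": 0.6, "intercept_confidence": 0.3,
               "slope0": 2.0, "slope_decision": 0.5, "slope_interaction": 0.7},
            pattern=t1.pattern,
        )
        ep2, _ = simulate_epochs(trials, t2, seed=5)
        pre1 = sliding_features(ep1, tmin_ms=0, tmax_ms=250)
        post1 = sliding_features(ep1, tmin_ms=300, tmax_ms=550)
        post2 = sliding_features(ep2, tmin_ms=300, tmax_ms=550)
        ens = train_decoders(pre1, ep1.labels["initial_choice"], scheme="all")
        base = decode_dv(ens, post1, train_post=post1)
        scaled = decode_dv(ens, post2, train_post=post1)
        # the frozen rule is affine: dv(x) = L(x) + offset with L linear,
        # offset = b - (mu/sd) . w; doubling the input doubles L exactly
        mu = post1.X.mean(axis=(0, 1))
        sd = post1.X.std(axis=(0, 1))
        sd = np.where(sd > 0, sd, 1.0)
        offset = ens.intercepts - ens.weights @ (mu / sd)  # per timepoint
        lin1 = base.dv - offset[None, :]
        lin2 = scaled.dv - offset[None, :]
        np.testing.assert_allclose(lin2, 2.0 * lin1, atol=1e-8)

    def test_high_snr_dv_sign_tracks_presented_direction(self, session_table):
        trials = session_table.iloc[:60].reset_index(drop=True)
        truth = EpochGroundTruth(
            n_channels=16, n_samples=121, post_onset_ms=300, window_ms=400,
            noise_scale=0.05, intercept0=0.0, intercept_confidence=0.0,
            spatial_corr_length=3.0,
        )
        ep, _ = simulate_epochs(trials, truth, seed=9)
        pre = sliding_features(ep, tmin_ms=0, tmax_ms=250)
        post = sliding_features(ep, tmin_ms=400, tmax_ms=650)
        ens = train_decoders(pre, ep.labels["initial_choice"], scheme="loo")
        dv = decode_dv(ens, post)
        s_dir = np.where(ep.labels["direction"] == "right", 1, -1)
        agree = np.mean(np.sign(dv.dv.mean(axis=1)) == s_dir)
        assert agree >= 0.95

    def test_timepoint_mismatch_rejected(self):
        feats, y = _blobs(T=3)
        ens = train_decoders(feats, y, scheme="all")
        short = SlidingFeatures(X=feats.X[:2], times_ms=feats.times_ms[:2])
        with pytest.raises(ValueError):
            decode_dv(ens, short)


class TestTrend:
    def test_constant_series(self):
        dv = neural.DVSeries(dv=np.full((3, 10), 1.7), times_ms=10.0 * np.arange(10))
        out = dv_trend(dv)
        np.testing.assert_allclose(out.slope, 0.0, atol=1e-12)
        np.testing.assert_allclose(out.intercept, 1.7)

    def test_exact_line_recovered(self):
        t = 10.0 * np.arange(20)
        dv = neural.DVSeries(dv=(0.2 + 1.5 * t / 1000.0)[None, :], times_ms=t)
        out = dv_trend(dv)
        assert out.intercept[0] == pytest.approx(0.2, abs=1e-10)
        assert out.slope[0] == pytest.approx(1.5, abs=1e-10)

    def test_matches_closed_form_least_squares(self):
        rng = np.random.default_rng(11)
        t = 10.0 * np.arange(30)
        Y = rng.normal(size=(100, 30))
        out = dv_trend(neural.DVSeries(dv=Y, times_ms=t))
        ts = t / 1000.0
        ts_c = ts - ts.mean()
        slope = (Y @ ts_c) / np.dot(ts_c, ts_c)
        intercept = Y.mean(axis=1) - slope * ts.mean()
        np.testing.assert_allclose(out.slope, slope, atol=1e-10)
        np.testing.assert_allclose(out.intercept, intercept, atol=1e-10)

    def test_degenerate_window_rejected(self):
        dv = neural.DVSeries(dv=np.zeros((2, 10)), times_ms=10.0 * np.arange(10))
        with pytest.raises(ValueError):
            dv_trend(dv, tmin_ms=0, tmax_ms=10)


class TestUnsign:
    def test_rightward_identity_leftward_negation_involution(self):
        s = pd.DataFrame({"intercept": [0.1, -0.2], "slope": [-0.3, 0.5]})
        d = ["right", "left"]
        out = unsign(s, d)
        assert out.slope[0] == pytest.approx(-0.3)  # rightward unchanged
        assert out.slope[1] == pytest.approx(-0.5)
        assert out.intercept[1] == pytest.approx(0.2)
        again = unsign(out, d)
        pd.testing.assert_frame_equal(again, s)

    def test_unknown_direction_rejected(self):
        with pytest.raises(ValueError):
            unsign(pd.DataFrame({"slope": [1.0]}), ["up"])


class TestPeakDecodability:
    def test_unimodal_peak_found(self):
        m = np.full((8, 8), 0.5)
        np.fill_diagonal(m, 0.6)
        m[5, 5] = 0.9
        assert peak_decodability(m) == 5

    def test_tie_breaks_to_earlier_timepoint(self):
        m = np.full((6, 6), 0.5)
        m[2, 2] = m[4, 4] = 0.9
        assert peak_decodability(m) == 2

    def test_agrees_with_exhaustive_scan(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            m = rng.uniform(0.4, 0.9, size=(12, 12))
            diag = np.diagonal(m)
            best = min(i for i in range(12) if diag[i] == diag.max())
            assert peak_decodability(m) == best

    def test_flat_diagonal_warns_and_returns_first(self):
        with pytest.warns(UserWarning):
            assert peak_decodability(np.full((5, 5), 0.5)) == 0


class TestAUC:
    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_auc_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=(30, 2, 2))
        y = np.where(rng.random(30) < 0.5, 1, -1)
        if len(np.unique(y)) < 2:
            y[0] = -y[1]
        base = neural._auc_matrix(scores, y)
        for f in (np.exp, np.tanh, lambda x: 3 * x + 7, lambda x: x**3):
            np.testing.assert_allclose(neural._auc_matrix(f(scores), y), base, atol=1e-12)


class TestSensorContributions:
    def _features(self, signal_channels, n=80, c=40, seed=0, amp=2.0):
        rng = np.random.default_rng(seed)
        y = np.repeat(["left", "right"], n // 2)
        X = rng.normal(size=(n, c))
        X[:, signal_channels] += amp * np.where(y == "right", 1.0, -1.0)[:, None]
        return X, y

    def test_signal_channels_rank_top_decile(self):
        sig = [3, 11, 19, 27, 35]
        X, y = self._features(sig)
        cmap = sensor_contributions(X, y, subset_size=8, reps=400, seed=1)
        order = np.argsort(cmap.contribution)[::-1]
        assert set(sig) <= set(order[: max(4, len(order) // 10) + len(sig)])
        assert np.all(cmap.counts > 0)

    def test_pure_noise_contributions_near_chance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(80, 30))
        y = np.repeat(["left", "right"], 40)
        cmap = sensor_contributions(X, y, subset_size=8, reps=300, seed=2)
        assert abs(cmap.contribution.mean() - 0.5) < 0.05
        assert cmap.contribution.max() - cmap.contribution.min() < 0.2

    def test_same_seed_identical_map(self):
        X, y = self._features([0, 1])
        a = sensor_contributions(X, y, subset_size=5, reps=50, seed=9)
        b = sensor_contributions(X, y, subset_size=5, reps=50, seed=9)
        np.testing.assert_array_equal(a.contribution, b.contribution)

    def test_insufficient_channels_rejected(self):
        X, y = self._features([0], c=5)
        with pytest.raises(ValueError):
            sensor_contributions(X, y, subset_size=30, reps=10, seed=0)


class TestTemporalGeneralization:
    def _cells(self, n, rng):
        # balanced cells within each half (the label halves are the two
        # choices), so every choice x cell stratum is feasible to fold
        base = np.tile(["high_stay", "low_stay", "high_com", "low_com"], n // 8 + 1)
        return np.concatenate([base[: n // 2], base[: n - n // 2]])

    def test_separable_data_auc_near_one_everywhere(self):
        rng = np.random.default_rng(21)
        feats, y = _blobs(n=64, sep=8.0, T=4)
        cells = self._cells(64, rng)
        tg = temporal_generalization(feats, feats, y, cells, folds=4, reps=2, seed=3)
        assert tg.overall.min() > 0.95

    def test_shuffled_labels_auc_near_half(self):
        rng = np.random.default_rng(23)
        feats, y = _blobs(n=96, sep=5.0, T=3)
        y_perm = rng.permutation(np.asarray(y))
        cells = self._cells(96, rng)
        tg = temporal_generalization(feats, feats, y_perm, cells, folds=4, reps=3, seed=4)
        se = np.sqrt(0.25 / 96)  # rough score-level SE
        assert np.all(np.abs(tg.overall - 0.5) < 0.5 * 0.3)
        assert abs(tg.overall.mean() - 0.5) < 3 * se

    def test_off_diagonal_hotspot_when_code_shifts_in_time(self):
        # signal present early in the pre phase and late in the post phase
        rng = np.random.default_rng(25)
        n, c = 64, 48
        y = np.repeat(["left", "right"], n // 2)
        sgn = np.where(np.asarray(y) == "right", 1.0, -1.0)
        pattern = rng.normal(size=c)
        pattern /= np.linalg.norm(pattern)
        pre = rng.normal(size=(4, n, c))
        post = rng.normal(size=(4, n, c))
        pre[0] += 1.5 * sgn[:, None] * pattern
        post[3] += 1.5 * sgn[:, None] * pattern
        tms = 10.0 * np.arange(4)
        tg = temporal_generalization(
            SlidingFeatures(pre, tms), SlidingFeatures(post, tms),
            y, self._cells(n, rng), folds=4, reps=10, seed=5,
        )
        assert tg.overall[0, 3] > 0.85
        assert tg.overall[0, 3] > tg.overall[0, 0] + 0.2
        assert tg.overall[0, 3] > tg.overall[3, 3] + 0.2

    def test_small_cell_raises_named_error(self):
        rng = np.random.default_rng(27)
        feats, y = _blobs(n=40, T=2)
        cells = np.array(["high_com"] * 2 + ["low_stay"] * 38)
        with pytest.raises(ValueError, match="high_com"):
            temporal_generalization(feats, feats, y, cells, folds=4, reps=1, seed=0)


class TestEndToEndRecovery:
    def test_injected_slopes_recovered_and_ordered(self, epoch_chain):
        """Full chain: epochs -> features -> LOO decoders -> DV -> trend ->
        unsign recovers the injected condition ordering and trial slopes."""
        epochs, truth, pre, post, ens, dv, unsigned = epoch_chain
        r = np.corrcoef(unsigned["slope"], truth.trial_slopes)[0, 1]
        assert r > 0.8
        dec = np.where(epochs.labels["initial_correct"] == 1, 1.0, -1.0)
        conf = np.where(epochs.labels["confidence_class"] == "high", 1.0, -1.0)
        m = unsigned["slope"].to_numpy()
        mean_conf_high = m[(dec > 0) & (conf > 0)].mean()
        mean_others = m[~((dec > 0) & (conf > 0))].mean()
        assert mean_conf_high > mean_others  # confirmatory-high is steepest

    def test_steeper_slopes_predict_faster_final_rts(self, epoch_chain, session_table):
        # DV validity: when the generator couples condition to both the
        # neural slope and behaviour, recovered slopes track final RT
        epochs, truth, *_, unsigned = epoch_chain
        trials = session_table.iloc[:80].reset_index(drop=True)
        r = np.corrcoef(unsigned["slope"], trials["final_rt"])[0, 1]
        assert r < 0  # steeper accumulation, faster responses
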