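"""Recursive PLS: moment recursions, cross-product updates, sessions."""

import dataclasses

import numpy as np
import pytest

from nironline.pls import pls_fit, pls_from_crossproducts, pls_predict
from nironline.preprocess import SpectraSet, msc_correct, msc_fit, sg_smooth
from nironline.rpls import (
    RPLSState,
    rpls_coefficients,
    rpls_init,
    rpls_update,
    run_online_session,
)


def _cal_data(rng, n=30, p=6):
    X = rng.normal(size=(n, p)) @ rng.normal(size=(p, p)) * 0.4
    y = X @ rng.normal(size=p) + rng.normal(scale=0.2, size=n)
    return X, y


class TestInit:
    def test_zero_update_state_reproduces_offline_model(self, rng):
        X, y = _cal_data(rng)
        state = rpls_init(X, y, n_lv=3)
        offline = pls_fit(X, y, 3)
        np.testing.assert_allclose(
            rpls_coefficients(state).coefficients, offline.coefficients,
            atol=1e-8)

    def test_proportional_single_feature_crossproducts(self):
        x = np.arange(1.0, 9.0)[:, None]
        y = 2.0 * x.ravel()
        state = rpls_init(x, y, n_lv=1)
        # autoscaled with the (N-1)-denominator convention
        assert state.XtX[0, 0] == pytest.approx(7.0, rel=1e-12)
        assert state.Xty[0] == pytest.approx(7.0, rel=1e-12)
        assert state.N == 8

    def test_zero_variance_feature_rejected(self, rng):
        X, y = _cal_data(rng)
        X[:, 1] = 3.3
        with pytest.raises(ValueError):
            rpls_init(X, y, n_lv=2)


class TestUpdate:
    def test_running_mean_equals_batch_mean(self, rng):
        X, y = _cal_data(rng)
        state = rpls_init(X, y, n_lv=2)
        Xs, ys = rng.normal(size=(25, 6)), rng.normal(size=25)
        for i in range(25):
            state = rpls_update(state, Xs[i], ys[i])
            all_X = np.vstack([X, Xs[: i + 1]])
            all_y = np.concatenate([y, ys[: i + 1]])
            np.testing.assert_allclose(state.x_mean, all_X.mean(0),
                                       rtol=0, atol=1e-12)
            assert state.y_mean == pytest.approx(all_y.mean(), abs=1e-12)
        assert state.N == 55

    def test_exact_variance_mode_tracks_batch_variance(self, rng):
        X, y = _cal_data(rng)
        state = rpls_init(X, y, n_lv=2, exact_variance=True)
        Xs, ys = rng.normal(size=(15, 6)), rng.normal(size=15)
        for i in range(15):
            state = rpls_update(state, Xs[i], ys[i])
        all_X = np.vstack([X, Xs])
        all_y = np.concatenate([y, ys])
        np.testing.assert_allclose(state.x_std, all_X.std(0, ddof=1),
                                   rtol=1e-10)
        assert state.y_std == pytest.approx(all_y.std(ddof=1), rel=1e-10)

    def test_printed_variance_never_below_exact(self, rng):
        X, y = _cal_data(rng)
        printed = rpls_init(X, y, n_lv=2)
        exact = rpls_init(X, y, n_lv=2, exact_variance=True)
        for _ in range(20):
            x_t = rng.normal(size=6) + 0.5  # shifted stream
            y_t = float(rng.normal()) + 1.0
            printed = rpls_update(printed, x_t, y_t)
            exact = rpls_update(exact, x_t, y_t)
            assert np.all(printed.x_std >= exact.x_std - 1e-12)
            assert printed.y_std >= exact.y_std - 1e-12

    def test_frozen_moments_lambda_one_equals_batch_crossproducts(self, rng):
        X, y = _cal_data(rng)
        state = rpls_init(X, y, n_lv=2, lam=1.0)
        state = dataclasses.replace(state, freeze_moments=True)
        XtX0, Xty0 = state.XtX.copy(), state.Xty.copy()
        Xs, ys = rng.normal(size=(12, 6)), rng.normal(size=12)
        for i in range(12):
            state = rpls_update(state, Xs[i], ys[i])
        Z = (Xs - state.x_mean) / state.x_std
        zy = (ys - state.y_mean) / state.y_std
        np.testing.assert_allclose(state.XtX, XtX0 + Z.T @ Z, rtol=0, atol=1e-10)
        np.testing.assert_allclose(state.Xty, Xty0 + Z.T @ zy, rtol=0, atol=1e-10)

    def test_lambda_zero_keeps_only_newest_sample(self, rng):
        X, y = _cal_data(rng)
        state = rpls_init(X, y, n_lv=1, lam=1.0)
        state = dataclasses.replace(state, lam=1e-12, freeze_moments=True)
        x_t = rng.normal(size=6)
        state = rpls_update(state, x_t, 0.7)
        z = (x_t - state.x_mean) / state.x_std
        np.testing.assert_allclose(state.XtX, np.outer(z, z), atol=1e-9)

    def test_forgetting_matches_unrolled_weighted_sum(self, rng):
        lam = 0.5
        X, y = _cal_data(rng)
        state = rpls_init(X, y, n_lv=2, lam=lam)
        state = dataclasses.replace(state, freeze_moments=True)
        XtX0 = state.XtX.copy()
        Xty0 = state.Xty.copy()
        Xs, ys = rng.normal(size=(10, 6)), rng.normal(size=10)
        for i in range(10):
            state = rpls_update(state, Xs[i], ys[i])
        t = 10
        expected_XtX = lam**t * XtX0
        expected_Xty = lam**t * Xty0
        for j in range(t):  # unrolled weighted-sum oracle
            z = (Xs[j] - state.x_mean) / state.x_std
            zy = (ys[j] - state.y_mean) / state.y_std
            expected_XtX += lam ** (t - 1 - j) * np.outer(z, z)
            expected_Xty += lam ** (t - 1 - j) * z * zy
        np.testing.assert_allclose(state.XtX, expected_XtX, atol=1e-10)
        np.testing.assert_allclose(state.Xty, expected_Xty, atol=1e-10)

    def test_non_finite_input_rejected(self, rng):
        X, y = _cal_data(rng)
        state = rpls_init(X, y, n_lv=1)
        with pytest.raises(ValueError):
            rpls_update(state, np.full(6, np.nan), 1.0)
        with pytest.raises(ValueError):
            rpls_update(state, np.zeros(5), 1.0)


class TestCoefficients:
    def test_duplicated_calibration_leaves_coefficients_unchanged(self, rng):
        """Feeding every calibration row once more (frozen scaling, λ=1)
        doubles the cross-products, which leaves the extracted regression
        vector identical to the offline one."""
        X, y = _cal_data(rng)
        state = rpls_init(X, y, n_lv=3, lam=1.0)
        state = dataclasses.replace(state, freeze_moments=True)
        XtX0 = state.XtX.copy()
        for i in range(len(y)):
            state = rpls_update(state, X[i], y[i])
        np.testing.assert_allclose(state.XtX, 2 * XtX0, atol=1e-9)
        np.testing.assert_allclose(
            rpls_coefficients(state).coefficients,
            pls_fit(X, y, 3).coefficients, atol=1e-8)

    def test_predictions_finite(self, rng):
        X, y = _cal_data(rng)
        state = rpls_init(X, y, n_lv=2, lam=0.9)
        for _ in range(8):
            state = rpls_update(state, rng.normal(size=6), float(rng.normal()))
        model = rpls_coefficients(state)
        preds = pls_predict(model, rng.normal(size=(5, 6)))
        assert np.all(np.isfinite(preds))

    def test_drift_free_stream_converges_to_batch_refit(self):
        """On an i.i.d. stream the online coefficients move toward the batch
        refit on the complete data."""
        rng = np.random.default_rng(21)
        X, y = _cal_data(rng, n=40, p=5)
        Xs, ys = _cal_data(rng, n=200, p=5)
        state = rpls_init(X, y, n_lv=3, lam=1.0)
        target = pls_fit(np.vstack([X, Xs]), np.concatenate([y, ys]), 3)
        dist = []
        for i in range(200):
            state = rpls_update(state, Xs[i], ys[i])
            if i in (9, 49, 199):
                dist.append(np.linalg.norm(
                    rpls_coefficients(state).coefficients - target.coefficients))
        assert dist[2] < dist[0]


class TestSession:
    def _study_pieces(self, default_study, offline_artifacts):
        import nironline as nl
        art = offline_artifacts
        online = default_study.online_stream
        si, pi = nl.split_calibration_prediction(online.y, (60, 15), 0)
        stream = SpectraSet(online.wavelengths, online.absorbance[si],
                            online.y[si])
        pred = SpectraSet(online.wavelengths, online.absorbance[pi],
                          online.y[pi])
        return art, stream, pred

    def test_empty_stream_reports_offline_metrics(self, default_study,
                                                  offline_artifacts):
        art, _, pred = self._study_pieces(default_study, offline_artifacts)
        state = rpls_init(art.X_cal[:, art.uve.selected], art.y_cal,
                          n_lv=art.n_lv, lam=1.0,
                          feature_indices=art.uve.selected)
        empty = SpectraSet(pred.wavelengths,
                           np.empty((0, pred.n_channels)),
                           np.empty(0))
        report = run_online_session(state, empty, pred,
                                    reference=art.reference)
        assert len(report.records) == 1
        rec = report.records[0]
        assert rec.iteration == 0 and rec.n_processed == 0
        # matches a direct evaluation of the same model on the same data
        corrected, _ = msc_correct(pred, art.reference)
        Xp = sg_smooth(corrected, 11, 2).absorbance[:, art.uve.selected]
        direct = pls_predict(rpls_coefficients(state), Xp)
        expected = float(np.sqrt(np.mean((pred.y - direct) ** 2)))
        assert rec.rmsep == pytest.approx(expected, rel=1e-12)

    def test_session_iteration_count_and_monitor(self, default_study,
                                                 offline_artifacts):
        import nironline as nl
        art, stream, pred = self._study_pieces(default_study, offline_artifacts)
        state, _ = nl.init_online_state(art, k_online=100, lam=0.85, seed=0)
        report = run_online_session(state, stream, pred,
                                    reference=art.reference, batch_size=5,
                                    monitor_m=30,
                                    calibration_spectra=art.calibration_spectra)
        assert len(report.records) == 13  # iteration 0 + 60/5 batches
        assert [r.n_processed for r in report.records] == list(range(0, 61, 5))
        for rep in report.monitor_reports:
            assert rep.eigenvalues.size == 30
            assert np.all(np.isfinite(rep.eigenvalues))
            assert len(rep.flagged_bands) == 30
        assert np.all(np.isfinite(report.rmsep_curve))

    def test_invalid_batch_size_rejected(self, default_study,
                                         offline_artifacts):
        art, stream, pred = self._study_pieces(default_study, offline_artifacts)
        state = rpls_init(art.X_cal[:, art.uve.selected], art.y_cal,
                          n_lv=art.n_lv, feature_indices=art.uve.selected)
        with pytest.raises(ValueError):
            run_online_session(state, stream, pred,
                               reference=art.reference, batch_size=0)
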