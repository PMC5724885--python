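import numpy as np
import pytest

from nirscal.mpls import (
    OutlierLimits,
    calibrate,
    detect_outliers,
    load_model,
    loocv,
    mpls_fit,
    predict,
    save_model,
)
from nirscal.simulate import SyntheticConfig, generate, plant_outliers


class TestMplsFit:
    def test_exact_two_factor_recovery(self, rng):
        # y an exact linear function of 2 latent spectral factors
        scores = rng.standard_normal((40, 2))
        loadings = rng.standard_normal((2, 30))
        X = scores @ loadings
        y = scores @ [1.5, -2.0]
        fit = mpls_fit(X, y, 2)
        assert fit.sec < 1e-8
        assert fit.r2c > 1 - 1e-12

    def test_single_informative_wavelength_matches_simple_regression(self, rng):
        x = rng.standard_normal(25)
        X = np.column_stack([x, np.zeros(25), np.zeros(25)])
        y = 3 * x + 0.5 + 0.01 * rng.standard_normal(25)
        with pytest.warns(UserWarning, match="constant wavelength"):
            fit = mpls_fit(X, y, 1)
        slope, intercept = np.polyfit(x, y, 1)
        np.testing.assert_allclose(fit.fitted, slope * x + intercept, atol=1e-8)

    def test_full_rank_equals_ols(self, rng):
        X = rng.standard_normal((20, 6))
        y = rng.standard_normal(20)
        fit = mpls_fit(X, y, 6)
        Xd = np.column_stack([np.ones(20), X])
        ols_fitted = Xd @ np.linalg.lstsq(Xd, y, rcond=None)[0]
        np.testing.assert_allclose(fit.fitted, ols_fitted, rtol=1e-6, atol=1e-8)

    def test_constant_y_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            mpls_fit(rng.standard_normal((10, 4)), np.ones(10), 2)

    def test_rank_limited_reduces_lv_with_warning(self, rng):
        x = rng.standard_normal(12)
        X = np.column_stack([x, 2 * x])  # rank 1
        y = x + 0.01 * rng.standard_normal(12)
        with pytest.warns(UserWarning, match="rank limited"):
            fit = mpls_fit(X, y, 2)
        assert fit.n_lv == 1


class TestLoocv:
    def test_equals_brute_force_loop(self, rng):
        X = rng.standard_normal((8, 5))
        y = X @ [1, 0.5, 0, -1, 2] + 0.1 * rng.standard_normal(8)
        secv, best, _ = loocv(X, y, 3)
        brute = np.empty((8, 3))
        for i in range(8):
            mask = np.ones(8, bool)
            mask[i] = False
            for a in range(1, 4):
                fit = mpls_fit(X[mask], y[mask], a)
                brute[i, a - 1] = fit.predict(X[i][None, :])[0]
        np.testing.assert_allclose(
            secv, np.sqrt(np.mean((brute - y[:, None]) ** 2, axis=0)), atol=1e-8
        )

    def test_noiseless_one_factor_selects_one_lv(self, rng):
        t = rng.standard_normal(30)
        X = np.outer(t, rng.standard_normal(12)) + 1e-9 * rng.standard_normal((30, 12))
        y = 2 * t + 1
        _, best, _ = loocv(X, y, 4)
        assert best == 1

    def test_best_never_worse_than_one_lv(self, rng):
        X = rng.standard_normal((20, 8))
        y = rng.standard_normal(20)
        secv, best, _ = loocv(X, y, 5)
        assert secv[best - 1] <= secv[0]

    def test_duplicated_rows_leak_information(self, rng):
        X = rng.standard_normal((12, 6))
        y = X @ rng.standard_normal(6) + 0.5 * rng.standard_normal(12)
        secv, best, _ = loocv(X, y, 3)
        secv_dup, best_dup, _ = loocv(np.vstack([X, X]), np.concatenate([y, y]), 3)
        assert secv_dup[best_dup - 1] < secv[best - 1]


class TestDetectOutliers:
    def test_centroid_sample_not_flagged(self, rng):
        X = rng.standard_normal((30, 10))
        y = X @ rng.standard_normal(10)
        X[0] = X[1:].mean(axis=0)  # near the centre of the cloud
        fit = mpls_fit(X, y, 2)
        flags = detect_outliers(fit, y, secv=1.0)
        assert 0 not in [i for i, _, _ in flags]

    def test_residual_three_times_secv_is_t_flagged(self, rng):
        X = rng.standard_normal((25, 6))
        y = X @ rng.standard_normal(6)
        fit = mpls_fit(X, y, 3)
        resid = np.abs(y - fit.fitted)
        # choose SECV so that exactly the largest residual exceeds 2.5x
        secv = resid.max() / 3.0
        flags = detect_outliers(fit, y, secv=secv)
        kinds = {i: k for i, k, _ in flags}
        assert kinds.get(int(np.argmax(resid))) == "t"

    def test_h_matches_brute_force_mahalanobis(self, rng):
        X = rng.standard_normal((40, 8))
        y = X @ rng.standard_normal(8) + 0.1 * rng.standard_normal(40)
        X[5] += 10.0  # planted far point
        fit = mpls_fit(X, y, 2)
        T = fit.scores
        Tc = T - T.mean(axis=0)
        cinv = np.linalg.inv(np.cov(T, rowvar=False))
        d2 = np.array([t @ cinv @ t for t in Tc]) / fit.n_lv
        flags = detect_outliers(fit, y, secv=1e9, limits=OutlierLimits(h_max=10))
        flagged = {i: v for i, k, v in flags if k == "H"}
        for i, h in enumerate(d2):
            if h > 10:
                assert i in flagged
                np.testing.assert_allclose(flagged[i], h, rtol=1e-8)


class TestCalibrate:
    def test_clean_set_has_no_outliers(self, coarse_dataset):
        spectra, refs = coarse_dataset
        model = calibrate(spectra, refs, "TCC", "SNVD+1111", max_lv=8)
        assert model.outlier_log == []
        assert model.stats["n_used"] == len(spectra)

    def test_rpd_is_sd_over_secv(self, coarse_dataset):
        spectra, refs = coarse_dataset
        model = calibrate(spectra, refs, "DMC", "SNVD+1111", max_lv=8)
        s = model.stats
        np.testing.assert_allclose(s["RPD"], s["SD"] / s["SECV"], rtol=1e-6)

    def test_gross_reference_error_is_t_flagged(self, coarse_dataset):
        spectra, refs = coarse_dataset
        bad_spectra, bad_refs, labels = plant_outliers(
            spectra, refs, n_ref_errors=1, magnitude=5, seed=3
        )
        model = calibrate(bad_spectra, bad_refs, "DMC", "SNVD+1111", max_lv=8)
        flagged = {sid for _, sid, kind, _ in model.outlier_log if kind == "t"}
        assert labels["reference"][0] in flagged

    def test_outlier_loop_monotone_and_bounded(self, coarse_dataset):
        spectra, refs = coarse_dataset
        bad_spectra, bad_refs, _ = plant_outliers(
            spectra, refs, n_ref_errors=2, n_spectral_errors=1, seed=5
        )
        limits = OutlierLimits(max_iterations=3)
        model = calibrate(bad_spectra, bad_refs, "DMC", "SNVD+1111", limits=limits, max_lv=8)
        iterations = [it for it, *_ in model.outlier_log]
        assert max(iterations) <= limits.max_iterations
        assert model.stats["n_used"] + len(model.outlier_log) == len(spectra)


class TestPredict:
    def test_training_set_reproduces_fitted_values(self, coarse_dataset):
        spectra, refs = coarse_dataset
        model = calibrate(spectra, refs, "DMC", "SNVD+1111", max_lv=8)
        sub_ids = set(model.sample_ids)
        idx = [i for i, sid in enumerate(spectra.sample_ids) if sid in sub_ids]
        from nirscal.sampling import subset

        pred = predict(model, subset(spectra, [spectra.sample_ids[i] for i in idx]))
        np.testing.assert_allclose(pred, model.fit.fitted, atol=1e-8)

    def test_grid_mismatch_rejected(self, coarse_dataset):
        spectra, refs = coarse_dataset
        model = calibrate(spectra, refs, "DMC", "SNVD+1111", max_lv=8)
        from nirscal.spectra import trim_resample

        other = trim_resample(spectra, 400, 2400, 20)
        with pytest.raises(ValueError, match="grid"):
            predict(model, other)

    def test_validation_r2_close_to_r2cv(self, coarse_dataset):
        spectra, refs = coarse_dataset
        model = calibrate(spectra, refs, "DMC", "SNVD+1111", max_lv=8)
        fresh_sp, fresh_refs = generate(
            SyntheticConfig(seed=99, grid=(400.0, 2500.0, 10.0), n_samples=120)
        )
        pred = predict(model, fresh_sp)
        from nirscal.stats import validation_stats

        result = validation_stats(pred, fresh_refs["DMC"].to_numpy())
        assert abs(result.R2p - model.stats["R2cv"]) < 0.05

    def test_serialization_round_trip(self, coarse_dataset, tmp_path):
        spectra, refs = coarse_dataset
        model = calibrate(spectra, refs, "TCC", "MSC+1111", max_lv=6)
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        np.testing.assert_allclose(
            predict(loaded, spectra), predict(model, spectra), atol=1e-10
        )
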