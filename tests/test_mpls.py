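"""MPLS engine: oracle equivalence, CV, GH scores, outlier protocol."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

import nirscal as nc
from nirscal.mpls import CVSettings, OutlierPolicy


def make_problem(seed, n=40, p=80, k=3, noise=0.0):
    """Low-rank spectra-like matrix with y a linear function of scores."""
    rng = np.random.default_rng(seed)
    scores = rng.normal(size=(n, k))
    loadings = rng.normal(size=(k, p))
    X = scores @ loadings + noise * rng.normal(size=(n, p))
    y = scores @ rng.normal(size=k) + noise * rng.normal(size=n)
    return X, y


class TestFit:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_standard_pls_with_scaling_off(self, seed):
        X, y = make_problem(seed, noise=0.05)
        model = nc.fit_mpls(X, y, 6, residual_scaling=False)
        for t in range(1, 7):
            ref = PLSRegression(n_components=t, scale=False).fit(X, y)
            np.testing.assert_allclose(
                model.predict_matrix(X, t), ref.predict(X).ravel(), atol=1e-6)

    def test_noiseless_mixture_recovered_exactly(self):
        X, y = make_problem(1, k=3, noise=0.0)
        model = nc.fit_mpls(X, y, 5)
        sec = np.sqrt(np.mean((model.predict_matrix(X, 3) - y) ** 2))
        assert sec <= 1e-6 * y.std()

    def test_linearity_in_y(self):
        X, y = make_problem(2, noise=0.05)
        m1 = nc.fit_mpls(X, y, 4)
        m2 = nc.fit_mpls(X, 2 * y, 4)
        for t in (1, 4):
            np.testing.assert_allclose(2 * m1.coefficients_by_terms[t],
                                       m2.coefficients_by_terms[t], atol=1e-10)

    def test_zero_variance_y_rejected(self):
        X, _ = make_problem(0)
        with pytest.raises(ValueError, match="variance"):
            nc.fit_mpls(X, np.ones(X.shape[0]), 3)

    def test_too_few_samples_rejected(self):
        X, y = make_problem(0, n=5)
        with pytest.raises(ValueError, match="max_terms"):
            nc.fit_mpls(X, y, 6)

    def test_sec_nonincreasing_while_factors_carry_signal(self):
        # each extra factor up to the generating rank removes real
        # variance, so SEC falls despite the shrinking df denominator
        X, y = make_problem(3, n=60, k=8, noise=0.0)
        model = nc.fit_mpls(X, y, 8)
        n = len(y)
        secs = []
        for t in range(1, 9):
            e = model.predict_matrix(X, t) - y
            secs.append(np.sqrt(np.sum(e**2) / (n - t - 1)))
        assert all(b <= a * (1 + 1e-9) for a, b in zip(secs, secs[1:]))

    def test_residual_sum_of_squares_nonincreasing(self):
        # the unnormalised fit error never increases with more terms
        X, y = make_problem(3, n=60, k=5, noise=0.1)
        model = nc.fit_mpls(X, y, 8)
        rss = [np.sum((model.predict_matrix(X, t) - y) ** 2) for t in range(1, 9)]
        assert all(b <= a + 1e-10 for a, b in zip(rss, rss[1:]))


class TestPredict:
    def test_self_consistency_on_training(self):
        X, y = make_problem(4, noise=0.05)
        model = nc.fit_mpls(X, y, 4)
        a = model.predict_matrix(X)
        b = nc.predict(model, X)
        np.testing.assert_array_equal(a, b)

    def test_single_sample_prediction(self):
        X, y = make_problem(5, noise=0.05)
        model = nc.fit_mpls(X, y, 4)
        batch = model.predict_matrix(X[:3])
        singles = [model.predict_matrix(X[i:i + 1])[0] for i in range(3)]
        np.testing.assert_allclose(batch, singles, atol=1e-12)

    def test_snv_invariance_propagates(self, rng):
        # scaling raw spectra before SNV leaves predictions untouched
        wl = 400.0 + 0.5 * np.arange(300)
        raw = rng.normal(size=(30, 300)).cumsum(axis=1)  # smooth-ish
        y = rng.normal(size=30)
        settings = nc.PreprocessingSettings(
            scatter_mode="snv", treatment=nc.MathTreatment(0, 0.0, 1, 1))
        sp = nc.SpectraSet([f"s{i}" for i in range(30)], wl, raw)
        pre = nc.apply_pipeline(sp, settings)
        model = nc.fit_mpls(pre.absorbance, y, 4)
        model.settings = settings
        model.training_grid = pre.wavelengths
        scaled = nc.SpectraSet(sp.sample_ids, wl, 3.7 * raw)
        np.testing.assert_allclose(nc.predict(model, scaled),
                                   nc.predict(model, sp), atol=1e-8)

    def test_grid_mismatch_rejected(self, rng):
        wl = 400.0 + 0.5 * np.arange(300)
        sp = nc.SpectraSet(["a", "b", "c"], wl,
                           rng.normal(size=(3, 300)))
        X, y = make_problem(6, n=30, p=263)
        model = nc.fit_mpls(X, y, 3)
        model.settings = nc.PreprocessingSettings()
        model.training_grid = wl[:200]
        with pytest.raises(ValueError, match="grid mismatch"):
            nc.predict(model, sp)


class TestCrossValidation:
    def test_loo_matches_brute_force(self):
        X, y = make_problem(7, n=25, p=40, noise=0.1)
        n = len(y)
        cv = CVSettings(n_groups=n, max_terms=4)
        secv, _ = nc.cross_validate(X, y, cv)
        # independent brute-force leave-one-out loop
        resid = np.empty((n, 4))
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            m = nc.fit_mpls(X[mask], y[mask], 4)
            for t in range(1, 5):
                resid[i, t - 1] = m.predict_matrix(X[i:i + 1], t)[0] - y[i]
        for t in range(1, 5):
            assert secv[t] == pytest.approx(np.sqrt(np.mean(resid[:, t - 1] ** 2)),
                                            abs=1e-12)

    def test_noiseless_data_selects_rank(self):
        X, y = make_problem(8, n=50, k=3, noise=0.0)
        secv, optimal = nc.cross_validate(X, y, CVSettings(n_groups=5, max_terms=6))
        assert optimal == 3
        assert secv[optimal] <= 1e-8 * y.std()

    def test_tolerance_never_selects_more_terms(self):
        X, y = make_problem(9, n=60, k=4, noise=0.3)
        _, t0 = nc.cross_validate(X, y, CVSettings(5, 8, 0.0))
        _, t5 = nc.cross_validate(X, y, CVSettings(5, 8, 0.05))
        assert t5 <= t0

    def test_cycling_assignment_is_deterministic(self):
        X, y = make_problem(10, noise=0.1)
        a = nc.cross_validate(X, y, CVSettings(5, 4))
        b = nc.cross_validate(X, y, CVSettings(5, 4))
        assert a == b


class TestGlobalH:
    def test_centroid_spectrum_has_gh_zero(self):
        X, y = make_problem(11, noise=0.1)
        model = nc.fit_mpls(X, y, 4)
        gh = nc.global_h(model, X.mean(axis=0, keepdims=True))
        assert gh[0] == pytest.approx(0.0, abs=1e-12)

    def test_calibration_mean_gh_is_one(self):
        X, y = make_problem(12, noise=0.1)
        model = nc.fit_mpls(X, y, 4)
        gh = nc.global_h(model, X)
        assert gh.mean() == pytest.approx(1.0, abs=1e-6)
        # brute-force Mahalanobis over scores confirms the constant
        T = model.cal_scores[:, :4]
        d = T - T.mean(axis=0)
        cov_inv = np.linalg.inv(np.cov(T, rowvar=False, ddof=1))
        d2 = np.einsum("ij,jk,ik->i", d, cov_inv, d)
        n = T.shape[0]
        np.testing.assert_allclose(gh, d2 / (4 * (n - 1) / n), atol=1e-10)

    def test_far_sample_exceeds_threshold(self):
        X, y = make_problem(13, noise=0.1)
        model = nc.fit_mpls(X, y, 4)
        T = model.cal_scores[:, :4]
        far = X.mean(axis=0) + 10 * T[:, 0].std() * model.weights[0]
        gh = nc.global_h(model, far[None, :])
        assert gh[0] > 3.0


class TestOutlierProtocol:
    def test_clean_data_identical_to_plain_fit(self):
        X, y = make_problem(14, n=60, noise=0.05)
        cv = CVSettings(5, 4)
        model, report = nc.calibrate_with_outlier_protocol(X, y, cv)
        if report["removed_round1"]:
            pytest.skip("random set contained a GH>3 sample")
        _, terms = nc.cross_validate(X, y, cv)
        plain = nc.fit_mpls(X, y, 4)
        np.testing.assert_array_equal(
            model.coefficients_by_terms[terms], plain.coefficients_by_terms[terms])

    def test_planted_scatter_outlier_removed_first_round(self):
        X, y = make_problem(15, n=60, noise=0.02)
        X_out = X.copy()
        X_out[7] = 5.0 * X[7] + 3.0  # extreme multiplicative + additive scatter
        ids = [f"s{i}" for i in range(60)]
        model, report = nc.calibrate_with_outlier_protocol(
            X_out, y, CVSettings(5, 4), OutlierPolicy(3.0), sample_ids=ids)
        assert "s7" in report["removed_round1"]
        assert report["reported_round2"] == {} or "s7" not in report["reported_round2"]

    def test_contaminated_sample_gh_monotone(self):
        X, y = make_problem(16, n=50, noise=0.05)
        base_model = nc.fit_mpls(X, y, 4)
        gh_clean = nc.global_h(base_model, X[5:6])[0]
        X2 = X.copy()
        X2[5] = 4.0 * X[5] + 2.0
        model2 = nc.fit_mpls(X2, y, 4)
        gh_dirty = nc.global_h(model2, X2[5:6])[0]
        assert gh_dirty >= gh_clean

    def test_protocol_deterministic(self):
        X, y = make_problem(17, n=60, noise=0.05)
        a = nc.calibrate_with_outlier_protocol(X, y, CVSettings(5, 4))
        b = nc.calibrate_with_outlier_protocol(X, y, CVSettings(5, 4))
        np.testing.assert_array_equal(
            a[0].coefficients_by_terms[a[0].selected_terms],
            b[0].coefficients_by_terms[b[0].selected_terms])
        assert a[1] == b[1]


class TestSerialization:
    def test_model_json_roundtrip(self, tmp_path):
        from nirscal.io import read_model_json, write_model_json
        X, y = make_problem(18, noise=0.05)
        model = nc.fit_mpls(X, y, 4)
        model.settings = nc.PreprocessingSettings()
        model.training_grid = 400.0 + 0.5 * np.arange(X.shape[1])
        path = tmp_path / "model.json"
        write_model_json(model, path, constituent="K")
        back = read_model_json(path)
        np.testing.assert_allclose(back.predict_matrix(X), model.predict_matrix(X),
                                   atol=1e-12)
        assert back.settings.treatment.code() == "2,8,6,1"
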