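"""DROP-D discriminant: algebraic invariants, oracles, parameter recovery."""

import numpy as np
import pytest

import hsretina as hs
from hsretina.dropd import _restrict_matrix
from hsretina.errors import CohortError, GridError, ModelError


def random_matrix(rng, n_case=8, n_control=10, p=91):
    grid = hs.human_grid()
    X = rng.normal(size=(n_case + n_control, p))
    labels = np.array(["case"] * n_case + ["control"] * n_control)
    return hs.SpectrumMatrix(X=X, labels=labels, grid=grid)


class TestFitInvariants:
    @pytest.mark.parametrize("k", [0, 1, 2, 5])
    def test_orthonormality_and_unit_axis(self, rng, k):
        model = hs.fit_dropd(random_matrix(rng), k)
        assert np.abs(np.linalg.norm(model.b) - 1) < 1e-12
        if k:
            assert np.abs(model.W.T @ model.W - np.eye(k)).max() < 1e-10
            assert np.abs(model.W.T @ model.b).max() < 1e-10
        else:
            assert model.W.shape == (91, 0)

    def test_k0_equals_bruteforce_mean_difference(self, rng):
        data = random_matrix(rng)
        model = hs.fit_dropd(data, 0)
        # independent oracle: direct subtraction of class means
        diff = data.X[data.labels == "case"].mean(0) - data.X[data.labels == "control"].mean(0)
        cos = abs(model.b @ diff) / np.linalg.norm(diff)
        assert cos >= 1 - 1e-10

    def test_case_mean_score_exceeds_control_mean(self, rng):
        data = random_matrix(rng)
        for k in (0, 2):
            model = hs.fit_dropd(data, k)
            s = hs.score_matrix(model, data)
            assert s[data.labels == "case"].mean() >= s[data.labels == "control"].mean()

    def test_deflation_idempotent(self, rng):
        data = random_matrix(rng)
        model = hs.fit_dropd(data, 3)
        P = np.eye(91) - model.W @ model.W.T
        Y = (data.X - model.mu) @ P
        np.testing.assert_allclose(Y @ P, Y, atol=1e-12)

    def test_k_bounds_and_single_class_rejected(self, rng):
        data = random_matrix(rng, 4, 4)
        with pytest.raises(ModelError):
            hs.fit_dropd(data, 7)
        X = rng.normal(size=(5, 91))
        with pytest.raises(CohortError):
            hs.fit_dropd(hs.SpectrumMatrix(X=X, labels=["case"] * 5, grid=hs.human_grid()), 0)

    def test_fit_is_deterministic(self, rng):
        data = random_matrix(rng)
        m1, m2 = hs.fit_dropd(data, 2), hs.fit_dropd(data, 2)
        np.testing.assert_array_equal(m1.b, m2.b)
        np.testing.assert_array_equal(m1.W, m2.W)


class TestScore:
    def test_training_mean_scores_zero(self, rng):
        data = random_matrix(rng)
        model = hs.fit_dropd(data, 2)
        assert hs.score(model, model.mu) == pytest.approx(0.0, abs=1e-12)

    def test_invariant_to_removed_axes(self, rng):
        data = random_matrix(rng)
        model = hs.fit_dropd(data, 3)
        x = rng.normal(size=91)
        for j in range(3):
            for alpha in (-7.3, 0.5, 40.0):
                moved = x + alpha * model.W[:, j]
                assert abs(hs.score(model, moved) - hs.score(model, x)) < 1e-9 * max(abs(alpha), 1)

    def test_translation_along_axis_adds_linearly(self, rng):
        data = random_matrix(rng)
        model = hs.fit_dropd(data, 1)
        x = rng.normal(size=91)
        t = 2.75
        assert hs.score(model, x + t * model.b) == pytest.approx(hs.score(model, x) + t)

    def test_grid_mismatch_rejected(self, rng):
        model = hs.fit_dropd(random_matrix(rng), 0)
        wrong = hs.Spectrum(values=np.zeros(47), grid=hs.make_grid(450, 680, 5), space="log")
        with pytest.raises(GridError):
            hs.score(model, wrong)

    def test_score_without_explicit_deflation_matches_deflated(self, rng):
        # scoring (x - mu) @ b equals scoring the deflated spectrum: b is
        # orthogonal to the removed axes by construction
        data = random_matrix(rng)
        model = hs.fit_dropd(data, 3)
        x = rng.normal(size=91)
        deflated = model.mu + (np.eye(91) - model.W @ model.W.T) @ (x - model.mu)
        assert hs.score(model, x) == pytest.approx(hs.score(model, deflated), abs=1e-10)


class TestModelOrderSelection:
    def test_two_planted_axes_select_k2(self, recovery_cohort):
        matrix, _ = recovery_cohort
        cv = hs.select_k_loocv(matrix, k_max=4)
        assert cv.chosen_k == 2
        assert cv.criterion[cv.chosen_k] == cv.criterion.max()

    def test_no_nuisance_selects_k0(self):
        cfg = hs.SyntheticCohortConfig(n_case=12, n_control=12, effect_size=15,
                                       noise_sd=0.002, nuisance_sds={}, seed=3)
        matrix, _ = hs.simulate_cohort(cfg)
        cv = hs.select_k_loocv(matrix, k_max=3)
        assert cv.chosen_k == 0

    def test_permuted_labels_flat_criterion(self):
        cfg = hs.recovery_cohort_config(seed=8)
        matrix, _ = hs.simulate_cohort(cfg)
        rng = np.random.default_rng(0)
        matrix.labels = rng.permutation(matrix.labels)
        cv = hs.select_k_loocv(matrix, k_max=3)
        assert np.all(np.abs(cv.criterion - 0.5) < 0.2)
        assert cv.flat

    def test_kmax_clipped_with_warning(self, rng):
        grid = hs.make_grid(450, 495, 5)
        X = rng.normal(size=(6, 10))
        labels = np.array(["case"] * 3 + ["control"] * 3)
        data = hs.SpectrumMatrix(X=X, labels=labels, grid=grid)
        with pytest.warns(UserWarning, match="clipped"):
            hs.select_k_loocv(data, k_max=10)


class TestConstituentFit:
    def test_pure_basis_column_recovered(self, basis):
        fit = hs.fit_constituents(basis.column("melanin"), basis)
        assert fit.coefficients["melanin"] == pytest.approx(1.0, abs=1e-8)
        for name, coef in fit.coefficients.items():
            if name != "melanin":
                assert abs(coef) < 1e-6
        assert fit.rmse_percent == pytest.approx(0.0, abs=1e-8)

    def test_orthogonal_axis_rmse_matches_projection_oracle(self, basis, rng):
        # build an axis orthogonal to every basis column and the intercept
        Q, _ = np.linalg.qr(np.column_stack([np.ones(91), basis.spectra]))
        v = rng.normal(size=91)
        v -= Q @ (Q.T @ v)
        v /= np.linalg.norm(v)
        fit = hs.fit_constituents(v, basis)
        expected = 100 * np.linalg.norm(v) / np.sqrt(91)
        assert fit.rmse_percent == pytest.approx(expected, rel=1e-9)

    def test_residual_orthogonal_to_fitted_subspace(self, basis, rng):
        v = rng.normal(size=91)
        fit = hs.fit_constituents(v, basis)
        design = np.column_stack([np.ones(91), basis.spectra])
        assert np.abs(design.T @ fit.residual).max() < 1e-10

    def test_planted_mixture_recovers_reported_residual_scale(self, basis, rng):
        # a within-class axis built as a known constituent mixture plus a
        # 0.004-SD residual should fit with RMSE ~0.4%
        true_coef = {"ocular_media": 0.7, "melanin": 0.5, "haemoglobin": 0.3}
        axis = sum(c * basis.column(n) for n, c in true_coef.items())
        axis = axis + rng.normal(0, 0.004, size=91)
        fit = hs.fit_constituents(axis, basis, include=list(true_coef))
        assert 0.25 < fit.rmse_percent < 0.55
        # exact OLS standard errors from the design's normal matrix
        sigma = 0.004
        design = np.column_stack([np.ones(91)] + [basis.column(n) for n in true_coef])
        cov = sigma**2 * np.linalg.inv(design.T @ design)
        for j, (name, c_true) in enumerate(true_coef.items(), start=1):
            se = np.sqrt(cov[j, j])
            assert abs(fit.coefficients[name] - c_true) < 3 * se


class TestResampleRecalibrate:
    def test_identity_on_same_grid(self, grid91, rng):
        s = hs.Spectrum(values=rng.normal(size=91), grid=grid91, space="log")
        np.testing.assert_array_equal(hs.resample_spectrum(s, grid91).values, s.values)

    def test_linear_spectrum_interpolated_exactly(self, grid91):
        s = hs.Spectrum(values=0.01 * grid91.values - 3, grid=grid91, space="log")
        fine = hs.make_grid(450, 900, 1)
        out = hs.resample_spectrum(s, fine)
        np.testing.assert_allclose(out.values, 0.01 * fine.values - 3, atol=1e-10)

    def test_mouse_grid_resampling_counts(self):
        src = hs.Spectrum(values=np.zeros(361), grid=hs.mouse_grid(), space="log")
        out = hs.resample_spectrum(src, hs.mouse_model_grid())
        assert len(out.values) == 47

    def test_extrapolation_rejected(self, grid91):
        s = hs.Spectrum(values=np.zeros(91), grid=grid91)
        with pytest.raises(GridError):
            hs.resample_spectrum(s, hs.make_grid(400, 900, 5))

    def test_recalibrate_same_grid_identical_model(self, recovery_cohort):
        matrix, _ = recovery_cohort
        direct = hs.fit_dropd(matrix, 2)
        recal = hs.recalibrate_model(matrix, matrix.grid, k=2)
        np.testing.assert_allclose(recal.b, direct.b, atol=1e-12)
        np.testing.assert_allclose(recal.W, direct.W, atol=1e-12)

    def test_recalibrated_model_preserves_discrimination(self, recovery_cohort):
        matrix, _ = recovery_cohort
        cv = hs.select_k_loocv(matrix, k_max=4)
        test, _ = hs.simulate_cohort(hs.recovery_cohort_config(seed=123))
        full = hs.fit_dropd(matrix, cv.chosen_k)
        auc_full = hs.roc_auc(hs.score_matrix(full, test), test.labels).auc
        mg = hs.mouse_model_grid()
        recal = hs.recalibrate_model(matrix, mg, k=cv.chosen_k)
        test_r = _restrict_matrix(test, mg)
        auc_recal = hs.roc_auc(hs.score_matrix(recal, test_r), test_r.labels).auc
        assert abs(auc_recal - auc_full) < 0.1

    def test_out_of_range_grid_rejected(self, recovery_cohort):
        matrix, _ = recovery_cohort
        with pytest.raises(GridError):
            hs.recalibrate_model(matrix, hs.make_grid(400, 680, 5), k=1)


class TestAggregateAndPersistence:
    @staticmethod
    def table_for(scores_by_loc, subject="A"):
        import pandas as pd
        rows = [
            {"subject_id": subject, "eye": "study", "location_id": loc, "score": s, "label": "case"}
            for loc, s in scores_by_loc.items()
        ]
        return hs.HSScoreTable(frame=pd.DataFrame(rows))

    def test_equal_scores_average_to_same(self):
        table = self.table_for({loc: 2.5 for loc in hs.LOCATIONS})
        out = hs.aggregate_scores(table)
        overall = out.frame[out.frame["location_id"] == "overall"]
        assert overall["score"].iloc[0] == pytest.approx(2.5)

    def test_one_to_six_averages_to_3p5(self):
        table = self.table_for(dict(zip(hs.LOCATIONS, [1, 2, 3, 4, 5, 6])))
        out = hs.aggregate_scores(table)
        assert out.frame.query("location_id == 'overall'")["score"].iloc[0] == pytest.approx(3.5)

    def test_location_order_irrelevant(self):
        fwd = self.table_for(dict(zip(hs.LOCATIONS, [1, 2, 3, 4, 5, 6])))
        rev = self.table_for(dict(zip(reversed(hs.LOCATIONS), [6, 5, 4, 3, 2, 1])))
        a = hs.aggregate_scores(fwd).frame.query("location_id == 'overall'")["score"].iloc[0]
        b = hs.aggregate_scores(rev).frame.query("location_id == 'overall'")["score"].iloc[0]
        assert a == b

    def test_missing_location_reported(self):
        table = self.table_for({loc: 1.0 for loc in hs.LOCATIONS[:-1]})
        with pytest.raises(CohortError, match="I2"):
            hs.aggregate_scores(table)

    def test_model_save_load_roundtrip(self, tmp_path, recovery_cohort):
        matrix, _ = recovery_cohort
        model = hs.fit_dropd(matrix, 2)
        back = hs.DropDModel.load(model.save(tmp_path / "model.json"))
        np.testing.assert_array_equal(back.b, model.b)
        np.testing.assert_array_equal(back.W, model.W)
        np.testing.assert_array_equal(back.mu, model.mu)
        assert back.grid == model.grid and back.k == model.k
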