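"""Regression core: OLS, influence diagnostics, outlier filter, training."""

import numpy as np
import pytest
from sklearn.base import clone

from ldff.features import FeatureVector, GenomeBins
from ldff.regress import (LDFFModel, LDFFRegressor, SingularDesignError,
                          compute_diagnostics, detect_outliers, fit_ols,
                          predict_ff, select_maf_cutoff, MAF_GRID)
from ldff.simdata import Confounders

from oracles import loo_diagnostics

CONF = Confounders(1.0, 0.95, 0.05)


def _random_instance(rng, n, p, noise=0.5):
    x = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = 1.0 + x @ beta + noise * rng.normal(size=n)
    return x, y


class TestFitOls:
    def test_interpolates_noiseless_affine_data(self, rng):
        x = rng.normal(size=(30, 3))
        y = 0.7 + x @ np.array([1.0, -2.0, 0.5])
        fit = fit_ols(x, y)
        assert np.allclose(fit.residuals, 0, atol=1e-10)
        assert np.allclose(fit.coef, [1.0, -2.0, 0.5], atol=1e-10)
        assert abs(fit.intercept - 0.7) < 1e-10

    def test_matches_closed_form_on_four_points(self):
        x = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([1.0, 2.0, 2.0, 4.0])
        fit = fit_ols(x, y)
        # closed-form simple regression
        slope = np.cov(x[:, 0], y, bias=True)[0, 1] / np.var(x[:, 0])
        intercept = y.mean() - slope * x.mean()
        assert abs(fit.coef[0] - slope) < 1e-12
        assert abs(fit.intercept - intercept) < 1e-12

    def test_matches_normal_equations_oracle(self, rng):
        x, y = _random_instance(rng, 40, 5)
        fit = fit_ols(x, y)
        design = np.column_stack([np.ones(40), x])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        assert np.allclose(np.r_[fit.intercept, fit.coef], beta, atol=1e-8)

    def test_singular_design_names_collinear_columns(self, rng):
        x = rng.normal(size=(20, 3))
        x[:, 2] = 2 * x[:, 0]  # exact collinearity
        with pytest.raises(SingularDesignError, match="rank deficient"):
            fit_ols(x, rng.normal(size=20), column_names=["a", "b", "c"])

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError, match="n > k"):
            fit_ols(rng.normal(size=(4, 4)), rng.normal(size=4))


class TestDiagnostics:
    def test_match_leave_one_out_refits(self, rng):
        """Studentized residuals, DFFITS, Cook's D and COVRATIO equal
        explicit leave-one-out recomputation."""
        for _ in range(10):
            x, y = _random_instance(rng, 20, 2)
            diag = compute_diagnostics(fit_ols(x, y)).table
            oracle = loo_diagnostics(x, y)
            for col in ["studentized", "dffits", "cooks_d", "covratio",
                        "leverage", "standardized"]:
                np.testing.assert_allclose(diag[col].to_numpy(), oracle[col],
                                           atol=1e-8, err_msg=col)

    def test_balanced_design_has_equal_leverage(self):
        # orthogonal +-1 design: every leverage equals (p+1)/n
        x = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]] * 3, dtype=float)
        y = np.arange(12, dtype=float)
        fit = fit_ols(x, y)
        assert np.allclose(fit.hat, 3 / 12, atol=1e-12)

    def test_duplicating_rows_shrinks_cooks_distance(self, rng):
        x, y = _random_instance(rng, 15, 2)
        d1 = compute_diagnostics(fit_ols(x, y)).table["cooks_d"]
        x2, y2 = np.vstack([x, x]), np.concatenate([y, y])
        d2 = compute_diagnostics(fit_ols(x2, y2)).table["cooks_d"]
        assert np.all(d2.to_numpy()[:15] < d1.to_numpy() + 1e-12)

    def test_degenerate_leverage_detected(self):
        x = np.array([[0.0], [0.0], [0.0], [0.0], [1000.0]])
        y = np.array([0.0, 0.1, -0.1, 0.05, 5.0])
        with pytest.raises(ValueError, match="leverage"):
            compute_diagnostics(fit_ols(x, y))


class TestOutlierFilter:
    def test_gross_y_outlier_hits_residual_criteria(self, rng):
        x = np.linspace(0, 1, 15).reshape(-1, 1)
        y = 2.0 + 3.0 * x[:, 0] + 0.01 * rng.normal(size=15)
        y[7] += 5.0  # gross response outlier at a low-leverage point
        fit = fit_ols(x, y)
        _, crit = detect_outliers(compute_diagnostics(fit), fit.n, fit.p)
        for key in ["max_abs_residual", "max_abs_studentized",
                    "max_abs_standardized", "max_cooks_d"]:
            assert crit[key] == [7], key

    def test_balanced_design_has_no_leverage_outliers(self):
        x = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1]] * 3, dtype=float)
        y = np.arange(12, dtype=float)
        fit = fit_ols(x, y)
        _, crit = detect_outliers(compute_diagnostics(fit), fit.n, fit.p)
        assert crit["high_leverage"] == []

    def test_dffits_threshold_formula(self, rng):
        # n=10, p=2 -> threshold 2*sqrt(3/10) ~ 1.0954
        x, y = _random_instance(rng, 10, 2)
        fit = fit_ols(x, y)
        diag = compute_diagnostics(fit)
        _, crit = detect_outliers(diag, 10, 2)
        thresh = 2 * np.sqrt(3 / 10)
        assert abs(thresh - 1.0954) < 1e-4
        expect = sorted(np.flatnonzero(
            diag.table["dffits"].abs() > thresh).tolist())
        assert crit["high_dffits"] == expect

    def test_union_is_single_pass(self, rng):
        x, y = _random_instance(rng, 25, 3)
        fit = fit_ols(x, y)
        union, crit = detect_outliers(compute_diagnostics(fit), fit.n, fit.p)
        assert union == sorted({i for ids in crit.values() for i in ids})


class TestLDFFRegressor:
    def test_sklearn_parameter_protocol(self):
        est = LDFFRegressor(remove_outliers=False)
        assert clone(est).get_params()["remove_outliers"] is False
        est.set_params(remove_outliers=True)
        assert est.get_params()["remove_outliers"] is True

    def test_noiseless_training_gives_perfect_fit(self, rng):
        x = rng.normal(size=(40, 4))
        y = 0.1 + x @ np.array([0.5, 0.2, -0.1, 0.05])
        est = LDFFRegressor().fit(x, y)
        assert est.training_mae_ < 1e-10
        assert est.training_r_ > 1 - 1e-9
        np.testing.assert_allclose(est.predict(x), y, atol=1e-8)

    def test_outlier_removal_restores_clean_fit(self, rng):
        x = rng.normal(size=(30, 2))
        y = 0.05 + x @ np.array([0.3, -0.2])
        y_noisy = y.copy()
        y_noisy[4] += 10.0
        est = LDFFRegressor().fit(x, y_noisy)
        assert 4 in est.outlier_indices_
        np.testing.assert_allclose(est.coef_, [0.3, -0.2], atol=1e-6)

    def test_predict_clamps_to_unit_interval(self, rng):
        x = rng.normal(size=(20, 2))
        y = rng.uniform(-0.5, 0.1, size=20)
        est = LDFFRegressor(remove_outliers=False).fit(x, y)
        clamped = est.predict(x, clamp=True)
        assert np.all((clamped >= 0) & (clamped <= 1))


def _toy_bins(n):
    return GenomeBins(chrom=np.array(["chr1"] * n, dtype=object),
                      start=np.arange(n, dtype=np.int64) * 5_000_000,
                      end=(np.arange(n) + 1).astype(np.int64) * 5_000_000)


class TestModelAndPrediction:
    def _model(self, coef, intercept=0.0, cutoff=0.2, n_bins=1):
        return LDFFModel(
            intercept=intercept, coefficients=np.asarray(coef, dtype=float),
            column_names=[f"bin_{i+1:04d}" for i in range(n_bins)]
            + ["total_coverage", "mq_gt0_coverage", "pcr_dup_rate"],
            maf_cutoff=cutoff, bin_fill_means=np.zeros(n_bins),
            removed_outliers=[], training_summary={})

    def test_zero_features_predict_the_intercept(self):
        m = self._model([0.0, 0.0, 0.0, 0.0], intercept=0.07)
        feat = FeatureVector("s", np.array([0.0]), Confounders(0, 0, 0), 0.2)
        raw, clamped = predict_ff(m, feat)
        assert raw == pytest.approx(0.07)

    def test_dot_product_and_clamping(self):
        m = self._model([2.0, 0.0, 0.0, 0.0])
        feat = FeatureVector("s", np.array([0.05]), Confounders(0, 0, 0), 0.2)
        assert predict_ff(m, feat)[0] == pytest.approx(0.10)
        m_neg = self._model([2.0, 0.0, 0.0, 0.0], intercept=-0.103)
        raw, clamped = predict_ff(m_neg, feat)
        assert raw == pytest.approx(-0.003)
        assert clamped == 0.0

    def test_cutoff_mismatch_rejected(self):
        m = self._model([1.0, 0.0, 0.0, 0.0], cutoff=0.2)
        feat = FeatureVector("s", np.array([0.05]), CONF, 0.3)
        with pytest.raises(ValueError, match="cutoff"):
            predict_ff(m, feat)

    def test_json_round_trip_preserves_predictions(self, tmp_path):
        from ldff.io import read_model_json, write_model_json
        m = self._model([2.0, 0.1, -0.2, 0.3], intercept=0.01)
        feat = FeatureVector("s", np.array([0.05]), CONF, 0.2)
        path = tmp_path / "model.json"
        write_model_json(m, str(path))
        m2 = read_model_json(str(path))
        assert predict_ff(m, feat) == predict_ff(m2, feat)


class _FakeTrackCohort:
    """Synthetic tracks where per-bin discordance is controlled exactly."""

    @staticmethod
    def build(rng, n_samples, n_bins=2, sites_per_bin=60, signal_maf=0.45,
              noise_maf=0.1, ff=None):
        from ldff.impute import GenotypeTrack
        from ldff.simdata import SiteTable
        tracks, ys = [], []
        n = n_bins * sites_per_bin
        pos = np.arange(1, n + 1) * (5_000_000 // sites_per_bin)
        maf = np.where(np.arange(n) % 2 == 0, signal_maf, noise_maf)
        for i in range(n_samples):
            f = rng.uniform(0.01, 0.3) if ff is None else ff[i]
            disc_p = np.where(maf == signal_maf, 0.05 + f, 0.3)
            observed = np.zeros(n, dtype=np.int8)
            imputed = (rng.random(n) < disc_p).astype(np.int8)
            post = np.zeros((n, 3))
            post[np.arange(n), imputed] = 1.0
            tracks.append(GenotypeTrack(
                sites=SiteTable(
                    chrom=np.array(["chr1"] * n, dtype=object),
                    pos=pos.astype(np.int64),
                    ref_allele=np.array(["A"] * n, dtype=object),
                    alt_allele=np.array(["C"] * n, dtype=object),
                    maf=maf),
                observed_gt=observed, imputed_posterior=post,
                imputed_gt=imputed))
            ys.append(f)
        return tracks, np.array(ys)


def _varied_confs(rng, n):
    return [Confounders(1.0 + 0.1 * rng.random(), 0.9 + 0.05 * rng.random(),
                        0.05 * rng.random()) for _ in range(n)]


class TestCutoffSelection:
    def test_single_element_grid_is_chosen(self, rng):
        tracks, y = _FakeTrackCohort.build(rng, 30)
        confs = _varied_confs(rng, 30)
        ids = [f"s{i}" for i in range(30)]
        cutoff, table, _ = select_maf_cutoff(tracks, confs, ids, y,
                                             _toy_bins(2), grid=[0.25])
        assert cutoff == 0.25
        assert len(table) == 1

    def test_default_grid_spans_published_values(self):
        assert MAF_GRID == (0.15, 0.2, 0.25, 0.3)

    def test_training_is_deterministic(self):
        """Training the same cohort twice yields byte-identical models."""
        import json

        from ldff.regress import train_ldff
        r1, r2 = np.random.default_rng(7), np.random.default_rng(7)
        out = []
        for r in (r1, r2):
            tracks, y = _FakeTrackCohort.build(r, 30)
            model = train_ldff(tracks, _varied_confs(r, 30),
                               [f"s{i}" for i in range(30)], y, _toy_bins(2),
                               grid=[0.15, 0.2])
            out.append(json.dumps(model.to_dict(), sort_keys=True))
        assert out[0] == out[1]

    def test_signal_only_above_cutoff_disfavors_low_cutoff(self, rng):
        """When discordance tracks FF only at high-MAF sites, a cutoff that
        admits the noise-only low-MAF sites loses the grid search."""
        wins = []
        for seed in range(3):
            r = np.random.default_rng(seed)
            tracks, y = _FakeTrackCohort.build(r, 40, signal_maf=0.45,
                                               noise_maf=0.18)
            cutoff, _, _ = select_maf_cutoff(
                tracks, _varied_confs(r, 40), [f"s{i}" for i in range(40)], y,
                _toy_bins(2), grid=[0.15, 0.2])
            wins.append(cutoff)
        assert all(c == 0.2 for c in wins)
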