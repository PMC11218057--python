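"""Model fitting, quality metrics, transforms, normalization, correlation."""

import math

import numpy as np
import pandas as pd
import pytest

from aggdoe.design import DesignTable, FactorSpec, ModelSpec, interaction_model
from aggdoe.modeling import (
    apply_transform,
    build_model_matrix,
    correlation_matrix,
    fit_mlr,
    invert_transform,
    model_validity,
    normalize_to_center_points,
    q2_press,
    replicate_groups_from_design,
    reproducibility,
    validity_from_pvalue,
)


def _square_design(extra_center=0):
    factors = [FactorSpec("A", 0, 1), FactorSpec("B", 0, 1)]
    coded = np.array([[-1, -1], [-1, 1], [1, -1], [1, 1]], dtype=float)
    if extra_center:
        coded = np.vstack([coded, np.zeros((extra_center, 2))])
    is_center = np.array([False] * 4 + [True] * extra_center)
    return DesignTable(factors, coded, is_center=is_center)


class TestModelMatrix:
    def test_two_level_factorial_is_orthogonal(self):
        X = build_model_matrix(_square_design(), interaction_model(["A", "B"])).to_numpy()
        np.testing.assert_allclose(X.T @ X, 4 * np.eye(4))

    def test_center_row_has_zero_nonintercept_entries(self):
        X = build_model_matrix(_square_design(1), interaction_model(["A", "B"]))
        np.testing.assert_allclose(X.to_numpy()[-1], [1, 0, 0, 0])

    def test_five_factor_interaction_width(self, campaign_design):
        X = build_model_matrix(campaign_design, interaction_model(campaign_design.factors))
        assert X.shape[1] == 16


class TestTransforms:
    def test_identity(self, rng):
        y = rng.normal(size=10)
        np.testing.assert_array_equal(apply_transform(y, "identity"), y)

    def test_neglog_values(self):
        assert apply_transform(np.array([100.0]), "neglog", eps=0)[0] == pytest.approx(0.0)
        assert apply_transform(np.array([10.0]), "neglog", eps=0)[0] == pytest.approx(1.0)

    def test_neglog_round_trip(self, rng):
        y = rng.uniform(1, 100, size=20)
        z = apply_transform(y, "neglog")
        np.testing.assert_allclose(invert_transform(z, "neglog"), y, rtol=1e-9)

    def test_nonpositive_argument_raises(self):
        with pytest.raises(ValueError, match="rows"):
            apply_transform(np.array([50.0, -100.0]), "neglog", eps=0.0)


class TestCenterNormalization:
    def _design(self):
        factors = [FactorSpec("A", 0, 1)]
        coded = np.array([[-1], [1], [0], [-1], [1], [0]], dtype=float)
        return DesignTable(
            factors,
            coded,
            run_ids=list("abcdef"),
            is_center=np.array([0, 0, 1, 0, 0, 1], bool),
            batch=np.array(["B1"] * 3 + ["B2"] * 3, object),
        )

    def test_identical_centers_is_identity(self):
        d = self._design()
        resp = pd.DataFrame({"y": [1.0, 2.0, 3.0, 4.0, 5.0, 3.0]}, index=list("abcdef"))
        out = normalize_to_center_points(resp, d)
        pd.testing.assert_frame_equal(out, resp)

    def test_doubled_batch_is_rescaled(self):
        d = self._design()
        resp = pd.DataFrame({"y": [1.0, 2.0, 2.0, 2.0, 4.0, 4.0]}, index=list("abcdef"))
        out = normalize_to_center_points(resp, d)
        grand = (2.0 + 4.0) / 2
        np.testing.assert_allclose(out["y"][:3], np.array([1, 2, 2.0]) * grand / 2.0)
        np.testing.assert_allclose(out["y"][3:], np.array([2, 4, 4.0]) * grand / 4.0)
        # grand center-point mean is preserved
        assert out["y"][[2, 5]].mean() == pytest.approx(grand)

    def test_idempotent(self):
        d = self._design()
        resp = pd.DataFrame({"y": [1.0, 2.0, 2.5, 2.0, 4.0, 4.0]}, index=list("abcdef"))
        once = normalize_to_center_points(resp, d)
        twice = normalize_to_center_points(once, d)
        pd.testing.assert_frame_equal(once, twice)

    def test_zero_center_mean_and_missing_center_raise(self):
        d = self._design()
        resp = pd.DataFrame({"y": [1.0, 2.0, 0.0, 2.0, 4.0, 4.0]}, index=list("abcdef"))
        with pytest.raises(ValueError, match="zero"):
            normalize_to_center_points(resp, d)
        with pytest.raises(ValueError, match="center"):
            normalize_to_center_points(resp.drop(index=["c"]).iloc[:2], d)


class TestFitMlr:
    def test_exact_recovery(self, rng):
        X = np.column_stack([np.ones(8), rng.normal(size=(8, 2))])
        beta = np.array([1.0, -2.0, 0.5])
        coef, se, lo, hi, r2, df, sigma2, _ = fit_mlr(X, X @ beta)
        np.testing.assert_allclose(coef, beta, atol=1e-9)
        assert r2 == pytest.approx(1.0)

    def test_orthogonal_contrast_formula(self):
        design = _square_design()
        X = build_model_matrix(design, interaction_model(["A", "B"])).to_numpy()
        y = np.array([3.0, 5.0, 7.0, 13.0])
        coef, *_ = fit_mlr(X, y)
        signs = X.T  # each coefficient is the signed quarter-sum of y
        np.testing.assert_allclose(coef, signs @ y / 4.0)

    def test_constant_response_r2_zero(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        r2 = fit_mlr(X, np.full(5, 2.0))[4]
        assert r2 == 0.0

    def test_rank_deficient_raises(self):
        X = np.column_stack([np.ones(5), np.arange(5.0), 2 * np.arange(5.0)])
        with pytest.raises(ValueError, match="rank"):
            fit_mlr(X, np.arange(5.0))


class TestQ2:
    def test_press_matches_explicit_loo_loop(self, rng):
        """Hat-matrix shortcut equals refitting with each row held out."""
        for _ in range(100):
            n, p = int(rng.integers(8, 15)), int(rng.integers(2, 5))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
            y = rng.normal(size=n)
            press = 0.0
            for i in range(n):
                mask = np.arange(n) != i
                beta = np.linalg.lstsq(X[mask], y[mask], rcond=None)[0]
                press += (y[i] - X[i] @ beta) ** 2
            q2_loop = 1.0 - press / np.sum((y - y.mean()) ** 2)
            assert q2_press(X, y) == pytest.approx(q2_loop, abs=1e-9)

    def test_q2_le_r2_always(self, rng):
        for _ in range(50):
            n = int(rng.integers(8, 20))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
            y = rng.normal(size=n)
            r2 = fit_mlr(X, y)[4]
            assert q2_press(X, y) <= r2 + 1e-12

    def test_noiseless_exact_model(self, rng):
        X = np.column_stack([np.ones(10), rng.normal(size=(10, 2))])
        y = X @ np.array([1.0, 2.0, -1.0])
        assert q2_press(X, y) == pytest.approx(1.0, abs=1e-9)

    def test_pure_noise_median_negative(self):
        """Leave-one-out punishes fitting noise: median Q2 < 0."""
        rng = np.random.default_rng(42)
        q2s = []
        for _ in range(1000):
            X = np.column_stack([np.ones(12), rng.normal(size=(12, 4))])
            q2s.append(q2_press(X, rng.normal(size=12)))
        assert np.median(q2s) < 0


class TestValidityAndReproducibility:
    def test_validity_threshold_correspondence(self):
        assert validity_from_pvalue(1.0) == pytest.approx(1.0)
        assert validity_from_pvalue(0.05) == pytest.approx(0.25, abs=1e-4)

    def test_validity_capped_at_one(self):
        assert validity_from_pvalue(0.999999) <= 1.0

    def test_no_replicates_gives_nan(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        assert math.isnan(model_validity(X, np.arange(5.0), []))

    def test_correct_model_median_validity_above_floor(self, rng):
        """A correctly specified model rarely shows lack of fit."""
        vals = []
        for _ in range(200):
            x = np.array([-1, -0.5, 0, 0.5, 1, 0, 0, 0.0])
            X = np.column_stack([np.ones(8), x])
            y = 1.0 + 2.0 * x + rng.normal(0, 0.3, size=8)
            groups = [np.array([2, 5, 6, 7])]
            vals.append(model_validity(X, y, groups))
        assert np.median(vals) > 0.25

    def test_reproducibility_limits(self):
        y = np.array([1.0, 2.0, 3.0, 2.0, 2.0])
        assert reproducibility(y, [np.array([3, 4])]) == pytest.approx(1.0)
        # replicate variance equal to half the total variance -> 0.5
        y2 = np.array([0.0, 4.0, 1.0, 3.0])
        var_tot = np.var(y2, ddof=1)
        g = [np.array([2, 3])]
        rep = reproducibility(y2, g)
        assert rep == pytest.approx(1.0 - 2.0 / var_tot)

    def test_replicate_groups_found_from_design(self, campaign_design):
        groups = replicate_groups_from_design(campaign_design)
        assert any(len(g) == 3 for g in groups)  # the 3 center points


class TestCorrelation:
    def test_self_and_exact_negative(self, rng):
        a = rng.normal(size=12)
        df = pd.DataFrame({"a": a, "b": -a})
        r, p = correlation_matrix(df)
        assert r.loc["a", "a"] == 1.0
        assert r.loc["a", "b"] == pytest.approx(-1.0)
        assert p.loc["a", "b"] < 1e-10

    def test_affine_invariance(self, rng):
        df = pd.DataFrame(rng.normal(size=(15, 3)), columns=list("xyz"))
        r1, _ = correlation_matrix(df)
        r2, _ = correlation_matrix(df * 7.0 - 3.0)
        np.testing.assert_allclose(r1.to_numpy(), r2.to_numpy(), atol=1e-12)

    def test_bivariate_normal_recovery(self):
        """mean r-hat over 2000 replicates of n=19 within 0.03 of rho=0.8."""
        rho, n = 0.8, 19
        rng = np.random.default_rng(7)
        cov = np.array([[1, rho], [rho, 1]])
        rs = []
        for _ in range(2000):
            xy = rng.multivariate_normal([0, 0], cov, size=n)
            rs.append(np.corrcoef(xy.T)[0, 1])
        df_mean = np.mean(rs)
        assert abs(df_mean - rho) < 0.03

    def test_too_few_pairs_raises(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0]})
        with pytest.raises(ValueError, match="pairs"):
            correlation_matrix(df)
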