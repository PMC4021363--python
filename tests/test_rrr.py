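import numpy as np
import pandas as pd
import pytest
from scipy import linalg

import dietrrr as d
from dietrrr import RRRError


def _standardized(rng, n, p, q, signal=0.4):
    X = rng.standard_normal((n, p))
    Y = X @ (rng.standard_normal((p, q)) * signal) + rng.standard_normal((n, q))
    Xdf = pd.DataFrame(X, columns=[f"food_{i}" for i in range(p)])
    Ydf = pd.DataFrame(Y, columns=[f"resp_{i}" for i in range(q)])
    return d.standardize(Xdf), d.standardize(Ydf)


class TestFit:
    def test_single_response_score_equals_standardized_ols_fit(self, rng):
        """With one response the fitted-response subspace is 1-dimensional,
        so the factor score must be the standardized OLS fitted values."""
        X, Y = _standardized(rng, 100, 5, 1)
        model = d.fit_rrr(X, Y, 1)
        Xv = X.values.to_numpy()
        yv = Y.values.to_numpy().ravel()
        fitted = Xv @ np.linalg.lstsq(Xv, yv, rcond=None)[0]
        fitted = (fitted - fitted.mean()) / fitted.std(ddof=1)
        r = np.corrcoef(model.scores.to_numpy().ravel(), fitted)[0, 1]
        assert abs(abs(r) - 1) < 1e-12

    def test_responses_in_predictor_span_fully_explained(self, rng):
        X, _ = _standardized(rng, 60, 4, 4)
        Y = d.StandardizedMatrix(
            values=X.values.copy(), means=X.means * 0, sds=X.sds * 0 + 1
        )
        model = d.fit_rrr(X, Y, 4)
        ev = d.explained_variation(model, X, Y)
        np.testing.assert_allclose(ev.loc[X.columns, "total"], 100.0, atol=1e-8)

    def test_eigenvalues_nonincreasing_and_loadings_orthonormal(self, random_xy):
        X, Y = random_xy
        model = d.fit_rrr(X, Y, 3)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)
        V = model.response_loadings.to_numpy()
        np.testing.assert_allclose(V.T @ V, np.eye(3), atol=1e-10)

    def test_training_scores_are_uncorrelated_zscores(self, random_xy):
        X, Y = random_xy
        model = d.fit_rrr(X, Y, 4)
        t = model.scores.to_numpy()
        np.testing.assert_allclose(t.mean(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(t.std(axis=0, ddof=1), 1, atol=1e-10)
        c = np.corrcoef(t.T) - np.eye(4)
        assert np.abs(c).max() < 1e-8

    def test_sign_convention_largest_weight_positive(self, random_xy):
        X, Y = random_xy
        model = d.fit_rrr(X, Y, 3)
        for f in model.factor_names:
            w = model.weights[f]
            assert w[w.abs().idxmax()] > 0

    def test_permutation_equivariance(self, rng):
        X, Y = _standardized(rng, 70, 5, 3)
        model = d.fit_rrr(X, Y, 2)
        perm = ["food_3", "food_0", "food_4", "food_1", "food_2"]
        Xp = d.StandardizedMatrix(
            values=X.values[perm], means=X.means[perm], sds=X.sds[perm]
        )
        model_p = d.fit_rrr(Xp, Y, 2)
        pd.testing.assert_frame_equal(model_p.weights, model.weights.loc[perm])
        pd.testing.assert_frame_equal(model_p.scores, model.scores, atol=1e-10, rtol=0)

    def test_negating_a_column_flips_its_weight_only(self, rng):
        X, Y = _standardized(rng, 70, 5, 3)
        model = d.fit_rrr(X, Y, 2)
        Xn_vals = X.values.copy()
        Xn_vals["food_2"] = -Xn_vals["food_2"]
        Xn = d.StandardizedMatrix(values=Xn_vals, means=X.means, sds=X.sds)
        model_n = d.fit_rrr(Xn, Y, 2)
        expected = model.weights.copy()
        expected.loc["food_2"] = -expected.loc["food_2"]
        # the factor-level sign convention may flip a whole factor if food_2
        # was the lead food; align factors by score correlation first
        for f in model.factor_names:
            r = np.corrcoef(model.scores[f], model_n.scores[f])[0, 1]
            s = np.sign(r)
            np.testing.assert_allclose(
                model_n.weights[f].to_numpy(), s * expected[f].to_numpy(), atol=1e-10
            )
            np.testing.assert_allclose(
                model_n.scores[f].to_numpy(), s * model.scores[f].to_numpy(), atol=1e-10
            )

    def test_errors(self, rng):
        X, Y = _standardized(rng, 40, 5, 3)
        with pytest.raises(RRRError, match="exceeds min"):
            d.fit_rrr(X, Y, 4)
        dup_vals = X.values.copy()
        dup_vals["food_4"] = dup_vals["food_3"]
        dup = d.StandardizedMatrix(values=dup_vals, means=X.means, sds=X.sds)
        with pytest.raises(RRRError, match="condition number"):
            d.fit_rrr(dup, Y, 2)
        Xs, Ys = _standardized(rng, 5, 6, 3)
        with pytest.raises(RRRError, match="participants"):
            d.fit_rrr(Xs, Ys, 2)


class TestOracle:
    def test_factor1_solves_generalized_eigenproblem(self, rng):
        """Independent oracle: the leading pattern weights must match the top
        generalized eigenvector of (S_xy S_yx, S_xx)."""
        X, Y = _standardized(rng, 60, 5, 3)
        model = d.fit_rrr(X, Y, 1)
        Xv, Yv = X.values.to_numpy(), Y.values.to_numpy()
        n = len(Xv)
        Sxx = Xv.T @ Xv / (n - 1)
        Sxy = Xv.T @ Yv / (n - 1)
        vals, vecs = linalg.eigh(Sxy @ Sxy.T, Sxx)
        a_star = vecs[:, -1]
        a_hat = model.weights.to_numpy().ravel()
        cos = abs(a_hat @ a_star) / (np.linalg.norm(a_hat) * np.linalg.norm(a_star))
        assert cos > 0.999999


class TestScores:
    def test_project_on_training_table_is_idempotent(self, small_cohort):
        i1, _, r1, _, _ = small_cohort
        X = d.standardize(i1.foods)
        Y = d.standardize(r1.values)
        model = d.fit_rrr(X, Y, 2)
        proj = d.project_scores(model, i1.foods)
        pd.testing.assert_frame_equal(proj, model.scores, atol=1e-10, rtol=0)

    def test_single_food_pattern_score_is_that_foods_zscore(self, rng):
        X, Y = _standardized(rng, 50, 4, 2)
        model = d.fit_rrr(X, Y, 1)
        model.weights.iloc[:, 0] = [1.0, 0.0, 0.0, 0.0]
        raw = pd.DataFrame(
            rng.gamma(2.0, 10.0, (30, 4)), columns=X.columns
        )
        proj = d.project_scores(model, raw)
        z = d.standardize(raw).values["food_0"]
        np.testing.assert_allclose(proj.iloc[:, 0], z, atol=1e-12)

    def test_missing_food_column_rejected(self, random_xy):
        X, Y = random_xy
        model = d.fit_rrr(X, Y, 2)
        with pytest.raises(ValueError, match="food"):
            d.project_scores(model, pd.DataFrame({"food_0": [1.0, 2.0]}))


class TestExplainedVariation:
    def test_conservation_sums_to_ols_r2(self, random_xy):
        """Summed over all q factors, per-response explained variation must
        equal 100 x the OLS R^2 of that response on the foods."""
        X, Y = random_xy
        q = Y.values.shape[1]
        model = d.fit_rrr(X, Y, q)
        ev = d.explained_variation(model, X, Y)
        Xv, Yv = X.values.to_numpy(), Y.values.to_numpy()
        B = np.linalg.lstsq(Xv, Yv, rcond=None)[0]
        resid = Yv - Xv @ B
        r2 = 1 - resid.var(axis=0, ddof=0) / Yv.var(axis=0, ddof=0)
        np.testing.assert_allclose(ev.loc[Y.columns, "total"], 100 * r2, atol=1e-8)

    def test_all_responses_row_is_mean_of_response_cells(self, random_xy):
        X, Y = random_xy
        model = d.fit_rrr(X, Y, 3)
        ev = d.explained_variation(model, X, Y)
        np.testing.assert_allclose(
            ev.loc["all_responses", model.factor_names],
            ev.loc[Y.columns, model.factor_names].mean(),
            atol=1e-12,
        )

    def test_single_food_single_response(self, rng):
        x = rng.standard_normal(30)
        X = d.standardize(pd.DataFrame({"a": x, "b": rng.standard_normal(30)}))
        Y = d.standardize(pd.DataFrame({"r": 2 * x + 1}))
        model = d.fit_rrr(X, Y, 1)
        ev = d.explained_variation(model, X, Y)
        assert ev.loc["r", "factor_1"] == pytest.approx(100.0, abs=1e-8)


class TestLabels:
    @staticmethod
    def _model_with_weights(w: dict):
        foods = list(w)
        weights = pd.DataFrame({"factor_1": pd.Series(w)})
        return d.RRRModel(
            weights=weights,
            response_loadings=pd.DataFrame({"factor_1": [1.0]}, index=["r"]),
            eigenvalues=np.array([1.0]),
            scores=pd.DataFrame(columns=["factor_1"]),
            food_loadings=weights.copy(),
            x_means=pd.Series(0.0, index=foods),
            x_sds=pd.Series(1.0, index=foods),
        )

    def test_negative_lead_weight_labels_low_in(self):
        model = self._model_with_weights({"high_fibre_bread": -0.27, "fruit_juices": 0.14})
        (lab,) = d.label_patterns(model, 0.10)
        assert lab["label"] == "(low in) high_fibre_bread"
        assert {f for f, _ in lab["high_weight"]} == {"high_fibre_bread", "fruit_juices"}

    def test_threshold_is_strict(self):
        model = self._model_with_weights({"a": 0.10, "b": 0.05})
        (lab,) = d.label_patterns(model, 0.10)
        assert lab["high_weight"] == []
        assert lab["label"] == "a"

    def test_degenerate_factor_still_labelled(self):
        model = self._model_with_weights({"a": 0.02, "b": -0.05})
        (lab,) = d.label_patterns(model, 0.10)
        assert lab["high_weight"] == []
        assert lab["label"] == "(low in) b"


def test_model_json_roundtrip(tmp_path, random_xy):
    X, Y = random_xy
    model = d.fit_rrr(X, Y, 2)
    path = model.to_json(tmp_path / "model.json")
    again = d.RRRModel.from_json(path)
    pd.testing.assert_frame_equal(model.weights, again.weights)
    pd.testing.assert_frame_equal(model.response_loadings, again.response_loadings)
    np.testing.assert_allclose(model.eigenvalues, again.eigenvalues)
    pd.testing.assert_series_equal(model.x_means, again.x_means)
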