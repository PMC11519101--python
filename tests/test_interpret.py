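"""Importance rankings and partial-dependence profiles."""

import numpy as np
import pandas as pd
import pytest

from recoverml.features import ColumnSpec
from recoverml.interpret import (
    ImportanceReport,
    aggregate_individual_importance,
    model_importance_scaled,
    partial_dependence,
    permutation_importance,
    top_k_features,
)
from recoverml.modeling import FitResult, fit_baseline, fit_group_model, make_learner
from recoverml.preprocess import UnfoldedDataset


def _dataset(betas, n_participants=5, n_rows=60, noise=0.5, seed=0, duplicate_first=False):
    rng = np.random.default_rng(seed)
    frames, ys, gs = [], [], []
    names = [f"x{j}" for j in range(len(betas))]
    for p in range(n_participants):
        X = rng.normal(size=(n_rows, len(betas)))
        if duplicate_first:
            X[:, 1] = X[:, 0]
        y = X @ np.array(betas) + rng.normal(0, noise, n_rows)
        frames.append(pd.DataFrame(X, columns=names))
        ys.append(pd.Series(y))
        gs.extend([f"P{p + 1}"] * n_rows)
    manifest = [ColumnSpec(n, "wellness", morning=True) for n in names]
    return UnfoldedDataset(
        X=pd.concat(frames, ignore_index=True),
        y=pd.concat(ys, ignore_index=True).rename("am_prs"),
        groups=pd.Series(gs),
        outcome="am_prs",
        manifest=manifest,
    )


class TestPermutationImportance:
    def test_null_feature_near_zero_and_signal_positive(self):
        ds = _dataset(betas=(3.0, 0.0), noise=0.5, seed=1)
        fit = fit_group_model(ds, "lasso", seed=0)
        rep = permutation_importance(fit, n_repeats=10, seed=0)
        t = rep.table.set_index("feature")
        # y = 3 x0 + eps: permuting x0 must raise the error substantially
        assert t.loc["x0", "importance"] > 1.0
        # the zero-coefficient feature contributes essentially nothing
        assert abs(t.loc["x1", "importance"]) < 0.01 * t.loc["x0", "importance"]

    def test_constant_feature_importance_exactly_zero(self):
        """Permuting a constant column is the identity permutation."""
        ds = _dataset(betas=(2.0, 0.0), seed=2)
        ds.X["x1"] = 1.0
        fit = fit_group_model(ds, "ridge", seed=0)
        rep = permutation_importance(fit, n_repeats=3, seed=0)
        assert rep.table.set_index("feature").loc["x1", "importance"] == 0.0

    def test_duplicated_pair_joint_exceeds_individual(self):
        ds = _dataset(betas=(1.5, 1.5, 0.0), duplicate_first=True, noise=0.3, seed=3)
        fit = fit_group_model(ds, "ridge", seed=0)
        rep = permutation_importance(fit, n_repeats=5, seed=0)
        t = rep.table.set_index("feature")["importance"]
        # model can reconstruct the signal from the twin: single-column
        # permutation understates what the pair carries jointly
        ds2 = _dataset(betas=(1.5, 1.5, 0.0), duplicate_first=True, noise=0.3, seed=3)
        ds2.X["x0"] = np.random.default_rng(0).permutation(ds2.X["x0"].to_numpy())
        ds2.X["x1"] = np.random.default_rng(1).permutation(ds2.X["x1"].to_numpy())
        joint_rmse = np.sqrt(
            np.mean(
                [
                    np.mean(
                        (
                            ds2.y.iloc[f["test_idx"]].to_numpy()
                            - f["estimator"].predict(ds2.X.iloc[f["test_idx"]].to_numpy(float))
                        )
                        ** 2
                    )
                    for f in fit.folds
                ]
            )
        )
        base_rmse = fit.result.rmse
        assert joint_rmse - base_rmse > max(t["x0"], t["x1"])

    def test_absent_feature_rejected(self):
        ds = _dataset(betas=(1.0,))
        fit = fit_group_model(ds, "ridge", seed=0)
        with pytest.raises(KeyError):
            permutation_importance(fit, features=["nope"])


class TestModelImportanceScaled:
    def _fit_result(self, X, y, learner="ridge"):
        est = make_learner(learner, 0)
        est.fit(X.to_numpy(float), np.asarray(y, float))
        return FitResult("am_prs", "individual", "MAIN", learner, 0.0, (0, 0), 0.0,
                         hyperparameters={"fitted": est})

    def test_single_driver_gets_full_importance(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(200, 3)), columns=["a", "b", "c"])
        y = 4.0 * X["a"]
        rep = model_importance_scaled(self._fit_result(X, y, "lasso"), X, y)
        t = rep.table.set_index("feature")["importance"]
        assert t["a"] == pytest.approx(1.0, abs=1e-6)

    def test_two_equal_drivers_split_evenly(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(400, 2)), columns=["a", "b"])
        y = X["a"] + X["b"]
        rep = model_importance_scaled(self._fit_result(X, y), X, y)
        t = rep.table.set_index("feature")["importance"]
        assert t["a"] == pytest.approx(0.5, abs=0.02)

    def test_importances_sum_to_one_and_nonnegative(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(100, 5)), columns=list("abcde"))
        y = X["a"] - 2 * X["c"] + rng.normal(0, 1, 100)
        for learner in ("ridge", "knn"):
            rep = model_importance_scaled(self._fit_result(X, y, learner), X, y)
            assert rep.table["importance"].sum() == pytest.approx(1.0, abs=1e-8)
            assert (rep.table["importance"] >= 0).all()

    def test_all_zero_importance_degrades_to_uniform(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(100, 4)), columns=list("abcd"))
        y = pd.Series(np.zeros(100))
        with pytest.warns(UserWarning, match="uniform"):
            rep = model_importance_scaled(self._fit_result(X, y, "lasso"), X, y)
        assert np.allclose(rep.table["importance"], 0.25)


class TestAggregateImportance:
    def _report(self, pairs):
        return ImportanceReport(
            table=pd.DataFrame({"feature": [p[0] for p in pairs], "importance": [p[1] for p in pairs], "sd": 0.0}),
            method="model_based_scaled",
        )

    def test_identical_reports_idempotent(self):
        r = self._report([("a", 0.7), ("b", 0.3)])
        agg = aggregate_individual_importance([r, r, r])
        got = dict(zip(agg["feature"], agg["importance"]))
        assert got["a"] == pytest.approx(0.7) and got["b"] == pytest.approx(0.3)

    def test_disjoint_single_feature_models_average_to_half(self):
        agg = aggregate_individual_importance(
            [self._report([("a", 1.0)]), self._report([("b", 1.0)])]
        )
        assert dict(zip(agg["feature"], agg["importance"])) == {"a": 0.5, "b": 0.5}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate_individual_importance([])


class TestPartialDependence:
    def test_linear_model_slope_equals_coefficient(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(300, 2)), columns=["a", "b"])
        y = 2.5 * X["a"] - 1.0 * X["b"]

        class OLS:
            def fit(self, X, y):
                self.beta = np.linalg.lstsq(np.asarray(X), np.asarray(y), rcond=None)[0]
                return self

            def predict(self, X):
                return np.asarray(X) @ self.beta

        model = OLS().fit(X, y)
        prof = partial_dependence(model, X, "a")
        assert prof.slope() == pytest.approx(2.5, abs=1e-6)
        resp = prof.mean_response
        np.testing.assert_allclose(np.diff(resp) / np.diff(prof.grid), 2.5, atol=1e-6)

    def test_feature_dropped_by_lasso_gives_flat_profile(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(200, 2)), columns=["a", "b"])
        y = (3.0 * X["a"]).to_numpy()
        est = make_learner("lasso", 0)
        est.fit(X.to_numpy(float), y)
        prof = partial_dependence(est, X, "b")
        assert np.ptp(prof.mean_response) < 1e-8

    def test_baseline_model_profile_flat(self, small_main_prs):
        fit = fit_baseline(small_main_prs)
        est = fit.folds[0]["estimator"]
        prof = partial_dependence(est, small_main_prs.X, "soreness")
        assert np.ptp(prof.mean_response) == 0.0

    def test_additive_model_pd_matches_marginal_component(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(400, 2)), columns=["a", "b"])
        beta = np.array([1.7, -0.8])

        class Additive:
            def predict(self, Z):
                return np.asarray(Z) @ beta

        prof = partial_dependence(Additive(), X, "a", grid_size=15)
        expected = beta[0] * prof.grid + beta[1] * X["b"].mean()
        np.testing.assert_allclose(prof.mean_response, expected, atol=1e-10)

    def test_zero_variance_feature_rejected(self):
        X = pd.DataFrame({"a": np.ones(50), "b": np.arange(50.0)})
        with pytest.raises(ValueError):
            partial_dependence(lambda: None, X, "a")


class TestTopK:
    def _report(self):
        return ImportanceReport(
            table=pd.DataFrame(
                {"feature": ["c", "a", "b", "d"], "importance": [0.4, 0.3, 0.3, 0.0], "sd": 0.0}
            ),
            method="permutation",
        )

    def test_k_zero_and_k_n(self):
        assert top_k_features(self._report(), 0) == []
        assert len(top_k_features(self._report(), 4)) == 4

    def test_sorted_with_alphabetical_ties(self):
        assert top_k_features(self._report(), 3) == ["c", "a", "b"]

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            top_k_features(self._report(), 9)
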