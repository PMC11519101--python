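"""Inclusion rules, imputation, correlation pruning, and lag unfolding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from recoverml.features import ColumnSpec
from recoverml.preprocess import (
    apply_inclusion_rules,
    impute_missing,
    markov_unfold,
    prune_correlated,
    select_variable_set,
)


def _mini_logs(weekly_hours, n_days=84, logged_fraction=1.0, pid="P1", start="2023-01-02"):
    dates = pd.date_range(start, periods=n_days).date.astype(str)
    minutes_per_day = weekly_hours * 60 / 7
    sessions = pd.DataFrame(
        {
            "participant_id": pid,
            "date": dates,
            "modality": "run",
            "duration_min": minutes_per_day,
            "rpe": 50.0,
            "pre_ex_cho_g": 30.0,
        }
    )
    rng = np.random.default_rng(0)
    daily = pd.DataFrame(
        {
            "participant_id": pid,
            "date": dates,
            "kcal": 2800.0,
            "cho_g_kg": 4.0,
            "fat_g_kg": 1.7,
            "protein_g_kg": 1.9,
            "sleep_h": 7.5,
            "sleep_quality": 5.0,
            "soreness": 4.0,
            "life_stress": 3.0,
            "am_prs": 60.0,
            "ln_rmssd": 4.0,
            "resting_hr": 55.0,
            "body_mass_kg": 70.0,
        }
    )
    if logged_fraction < 1.0:
        cols = ["sleep_h", "sleep_quality", "soreness", "life_stress", "resting_hr"]
        mask = rng.random((n_days, len(cols))) > logged_fraction
        for j, c in enumerate(cols):
            daily.loc[mask[:, j], c] = np.nan
    return sessions, daily


class TestInclusionRules:
    def test_low_volume_excluded(self):
        s, d = _mini_logs(weekly_hours=5.9)
        _, _, rep = apply_inclusion_rules(s, d)
        row = rep.table.iloc[0]
        assert not row["included"] and "low_volume" in row["reasons"]

    def test_low_logging_excluded(self):
        s, d = _mini_logs(weekly_hours=8.0, logged_fraction=0.55)
        _, _, rep = apply_inclusion_rules(s, d)
        row = rep.table.iloc[0]
        assert not row["included"] and "low_logging" in row["reasons"]

    def test_adequate_participant_included(self):
        s, d = _mini_logs(weekly_hours=8.0, n_days=50)
        filt_s, filt_d, rep = apply_inclusion_rules(s, d)
        assert rep.table.iloc[0]["included"]
        assert len(filt_d) == 50

    def test_short_tracking_excluded(self):
        s, d = _mini_logs(weekly_hours=8.0, n_days=30)
        _, _, rep = apply_inclusion_rules(s, d)
        assert "short_tracking" in rep.table.iloc[0]["reasons"]

    def test_incomplete_diet_days_removed_first(self):
        s, d = _mini_logs(weekly_hours=8.0, n_days=50)
        d.loc[3, "kcal"] = np.nan
        _, filt_d, rep = apply_inclusion_rules(s, d)
        assert len(filt_d) == 49
        assert rep.table.iloc[0]["days_tracked"] == 49


class TestImputeMissing:
    def test_single_missing_cho_filled_locally(self):
        _, d = _mini_logs(weekly_hours=8.0, n_days=40)
        d["cho_g_kg"] = np.random.default_rng(1).normal(4.0, 0.5, len(d))
        original = d.copy()
        d.loc[10, "cho_g_kg"] = np.nan
        out = impute_missing(d)
        assert out["cho_g_kg"].notna().all()
        untouched = out.drop(index=10)
        pd.testing.assert_frame_equal(
            untouched.reset_index(drop=True),
            original.drop(index=10).reset_index(drop=True),
        )

    def test_missing_wellness_filled_with_participant_median(self):
        _, d = _mini_logs(weekly_hours=8.0, n_days=30)
        d["soreness"] = 3.0
        d.loc[[5, 6], "soreness"] = np.nan
        out = impute_missing(d)
        assert (out["soreness"] == 3.0).all()

    def test_idempotent_on_complete_table(self):
        _, d = _mini_logs(weekly_hours=8.0, n_days=30)
        out = impute_missing(d)
        pd.testing.assert_frame_equal(out.reset_index(drop=True), d.reset_index(drop=True))

    def test_fully_missing_column_rejected(self):
        _, d = _mini_logs(weekly_hours=8.0, n_days=30)
        d["soreness"] = np.nan
        with pytest.raises(ValueError, match="P1.*soreness"):
            impute_missing(d)


def _bruteforce_prune(X: pd.DataFrame, threshold: float):
    """Direct restatement of the pruning rule, used as an oracle."""
    cols = [c for c in X.columns if X[c].std(ddof=1) > 0]
    while len(cols) > 1:
        corr = X[cols].corr().abs()
        best, pair = 0.0, None
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                if corr.iloc[i, j] > best:
                    best, pair = corr.iloc[i, j], (i, j)
        if best <= threshold or pair is None:
            break
        i, j = pair
        mean_i = (corr.iloc[i].sum() - 1) / (len(cols) - 1)
        mean_j = (corr.iloc[j].sum() - 1) / (len(cols) - 1)
        cols.pop(i if mean_i >= mean_j else j)
    return cols


class TestPruneCorrelated:
    def test_duplicate_column_removed(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=100)
        X = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.normal(size=100)})
        pruned, removed = prune_correlated(X)
        assert pruned.shape[1] == 2
        assert "c" in pruned.columns
        corr = pruned.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0)
        assert corr.max() <= 0.85

    def test_uncorrelated_matrix_untouched(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        pruned, removed = prune_correlated(X)
        assert list(pruned.columns) == list("abcd") and not removed

    def test_constant_column_dropped_with_reason(self):
        X = pd.DataFrame({"a": np.ones(50), "b": np.arange(50.0), "c": np.random.default_rng(2).normal(size=50)})
        pruned, removed = prune_correlated(X)
        assert ("a", "zero_variance") in removed

    def test_matches_bruteforce_oracle_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            z = rng.normal(size=(80, 2))
            X = pd.DataFrame(
                {
                    f"x{k}": z[:, rng.integers(0, 2)] * rng.uniform(0.5, 2)
                    + rng.normal(scale=rng.uniform(0.05, 1.0), size=80)
                    for k in range(5)
                }
            )
            got = list(prune_correlated(X, 0.85)[0].columns)
            want = _bruteforce_prune(X, 0.85)
            assert got == want

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 5000))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=(60, 2))
        X = pd.DataFrame(
            {f"x{k}": base[:, k % 2] + rng.normal(scale=0.3, size=60) for k in range(5)}
        )
        once, _ = prune_correlated(X)
        twice, removed2 = prune_correlated(once)
        assert list(once.columns) == list(twice.columns) and not removed2


def _toy_manifest(dynamic, static=()):
    specs = [ColumnSpec(c, "wellness", morning=True) for c in dynamic]
    specs += [ColumnSpec(c, "static", morning=True, dynamic=False) for c in static]
    specs.append(ColumnSpec("am_prs_c", "prs", morning=True, actionable=False))
    specs.append(ColumnSpec("hrv_change", "hrv", morning=True, actionable=False))
    return specs


def _toy_table(n_rows, dynamic, static=(), n_participants=1, seed=0):
    rng = np.random.default_rng(seed)
    parts = []
    for p in range(n_participants):
        df = pd.DataFrame(
            {c: rng.normal(size=n_rows) for c in list(dynamic) + ["am_prs_c", "hrv_change"]}
        )
        for c in static:
            df[c] = float(p)
        df.insert(0, "date", pd.date_range("2023-01-02", periods=n_rows).astype(str))
        df.insert(0, "participant_id", f"P{p + 1}")
        parts.append(df)
    return pd.concat(parts, ignore_index=True)


class TestMarkovUnfold:
    def test_toy_row_and_column_counts(self):
        dyn = ["a", "b", "c"]
        table = _toy_table(10, dyn)
        ds = markov_unfold(table, _toy_manifest(dyn), "am_prs", n_lags=7)
        assert len(ds.X) == 3
        dyn_cols = [c for c in ds.X.columns if ds.base_of(c) in dyn]
        assert len(dyn_cols) == 3 * 8  # n_lags + 1 copies per dynamic column

    def test_zero_lags_is_identity(self):
        dyn = ["a", "b"]
        table = _toy_table(6, dyn)
        ds = markov_unfold(table, _toy_manifest(dyn), "am_prs", n_lags=0)
        assert len(ds.X) == 6
        np.testing.assert_allclose(ds.X["a"], table["a"])

    def test_lagged_cells_match_direct_indexing(self):
        dyn = ["a", "b", "c"]
        table = _toy_table(15, dyn, n_participants=2, seed=3)
        n_lags = 4
        ds = markov_unfold(table, _toy_manifest(dyn), "am_prs", n_lags=n_lags)
        for pid, g in table.groupby("participant_id"):
            sub = ds.X[(ds.groups == pid).to_numpy()].reset_index(drop=True)
            base = g.reset_index(drop=True)
            for c in dyn:
                for k in range(1, n_lags + 1):
                    np.testing.assert_allclose(
                        sub[f"{c}__lag{k}"],
                        base[c].iloc[n_lags - k : len(base) - k],
                        err_msg=f"{c} lag{k} {pid}",
                    )

    def test_rows_per_participant_and_no_cross_participant_rows(self):
        dyn = ["a"]
        table = _toy_table(12, dyn, n_participants=3, seed=1)
        ds = markov_unfold(table, _toy_manifest(dyn), "am_prs", n_lags=7)
        assert (ds.groups.value_counts() == 12 - 7).all()

    def test_short_participant_dropped_with_warning(self):
        dyn = ["a"]
        t1 = _toy_table(12, dyn, seed=1)
        t2 = _toy_table(5, dyn, seed=2)
        t2["participant_id"] = "P9"
        table = pd.concat([t1, t2], ignore_index=True)
        with pytest.warns(UserWarning, match="P9"):
            ds = markov_unfold(table, _toy_manifest(dyn), "am_prs", n_lags=7)
        assert set(ds.groups) == {"P1"}

    def test_outcome_family_blocked_at_lag0(self, small_features):
        table, manifest, om = small_features
        ds_prs = markov_unfold(table, manifest, "am_prs", 7, outcome_missing=om)
        assert "am_prs_c" not in ds_prs.X.columns
        assert "am_prs_c__lag1" in ds_prs.X.columns
        ds_hrv = markov_unfold(table, manifest, "hrv_change", 7, outcome_missing=om)
        for col in ("hrv_change", "ln_rmssd", "resting_hr", "ewma_hrv", "ma7_hr"):
            assert col not in ds_hrv.X.columns
            assert f"{col}__lag1" in ds_hrv.X.columns


class TestSelectVariableSet:
    def test_actionable_excludes_monitoring_readouts(self, small_features):
        table, manifest, om = small_features
        ds = markov_unfold(table, manifest, "am_prs", 7, outcome_missing=om)
        act = select_variable_set(ds, "ACTIONABLE")
        banned_bases = {
            "am_prs_c", "sleep_index", "ma7_sleep_index", "sleep_quality",
            "ln_rmssd", "hrv_change", "ma7_hrv", "ewma_hrv",
            "resting_hr", "hr_change", "ma7_hr", "ewma_hr",
        }
        assert not {act.base_of(c) for c in act.X.columns} & banned_bases

    def test_main_is_superset_of_actionable(self, small_features):
        table, manifest, om = small_features
        ds = markov_unfold(table, manifest, "am_prs", 7, outcome_missing=om)
        main = set(select_variable_set(ds, "MAIN").X.columns)
        act = set(select_variable_set(ds, "ACTIONABLE").X.columns)
        assert act < main

    def test_top5_exact_columns(self, small_features):
        table, manifest, om = small_features
        ds = markov_unfold(table, manifest, "am_prs", 7, outcome_missing=om)
        want = ["soreness", "life_stress", "sleep_quality", "am_prs_c__lag1", "tl__lag1"]
        top = select_variable_set(ds, "TOP5", top5=want)
        assert list(top.X.columns) == want

    def test_unknown_set_rejected(self, small_main_prs):
        with pytest.raises(ValueError, match="unknown"):
            select_variable_set(small_main_prs, "EVERYTHING")
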