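"""Cohort inclusion rules, imputation, predictor pruning, and lag unfolding.

The unfolding step turns each participant's daily time series into rows that
can be treated as independent observations: every dynamic column is copied
at lags 1..n and stacked as new columns, and the first n rows of each
participant are discarded (they would reference days before the start of
tracking).  The design matrix is then n+1 times wider in its dynamic block.

Leakage policy: variables observed at or before the morning measurement
(sleep, wellness, HRV, resting HR) may enter at lag 0; variables accrued
over the rest of the day (training, diet and their rolling summaries) enter
at lags 1..n only, unless ``same_day_policy='all_lag0'`` is requested for
exploratory use.  Columns in the outcome's own family are never admitted at
lag 0 (the day's HRV reading determines the day's HRV change exactly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .features import ColumnSpec, OUTCOME_COLUMNS

__all__ = [
    "InclusionReport",
    "UnfoldedDataset",
    "apply_inclusion_rules",
    "impute_missing",
    "impute_features",
    "prune_correlated",
    "markov_unfold",
    "select_variable_set",
]

#: public outcome name -> feature-table column holding it
OUTCOME_TO_COLUMN = {"am_prs": "am_prs_c", "am_prs_c": "am_prs_c", "hrv_change": "hrv_change"}
#: families concurrent with each outcome column, blocked at lag 0 (the
#: morning HRV/HR readings come from the same measurement as HRV change)
_OUTCOME_FAMILY = {"am_prs_c": ("prs",), "hrv_change": ("hrv", "hr")}

DIET_TRAINING_COLUMNS = ("kcal", "cho_g_kg", "fat_g_kg", "protein_g_kg")


class EmptyCohortError(ValueError):
    """No participant survived the inclusion rules."""


@dataclass
class InclusionReport:
    table: pd.DataFrame  # participant_id, weekly_hours, logged_fraction, days_tracked, included, reasons

    @property
    def included_ids(self) -> list[str]:
        return list(self.table.loc[self.table["included"], "participant_id"])


@dataclass
class UnfoldedDataset:
    """Lag-stacked design matrix whose rows are independent observations."""

    X: pd.DataFrame
    y: pd.Series
    groups: pd.Series  # participant id per row
    outcome: str
    manifest: list[ColumnSpec] = field(default_factory=list)
    n_lags: int = 7

    def base_of(self, column: str) -> str:
        return column.split("__lag")[0]

    def columns_for(self, base: str) -> list[str]:
        return [c for c in self.X.columns if self.base_of(c) == base]


def apply_inclusion_rules(
    sessions: pd.DataFrame,
    daily: pd.DataFrame,
    min_weekly_hours: float = 6.0,
    min_logged_fraction: float = 0.85,
    min_days: int = 42,
) -> tuple[pd.DataFrame, pd.DataFrame, InclusionReport]:
    """Filter the cohort to adequately training, adequately logging athletes.

    Incomplete diet days (no energy intake recorded) are removed first, then
    a participant is retained iff average training volume >= 6 h/week, the
    fraction of logged predictor cells >= 85%, and >= 42 tracked days.
    """
    daily = daily.copy()
    incomplete = daily["kcal"].isna()
    daily = daily.loc[~incomplete].reset_index(drop=True)

    check_cols = [
        c
        for c in daily.columns
        if c not in ("participant_id", "date", "am_prs", "ln_rmssd")
    ]
    rows = []
    for pid, g in daily.groupby("participant_id", sort=True):
        days = len(g)
        span_days = days if days == 0 else (
            (pd.to_datetime(g["date"]).max() - pd.to_datetime(g["date"]).min()).days + 1
        )
        s = sessions[sessions["participant_id"] == pid]
        hours = s["duration_min"].sum() / 60.0
        weekly = hours / (span_days / 7.0) if span_days else 0.0
        logged = 1.0 - g[check_cols].isna().to_numpy().mean() if days else 0.0
        reasons = []
        if weekly < min_weekly_hours:
            reasons.append("low_volume")
        if logged < min_logged_fraction:
            reasons.append("low_logging")
        if days < min_days:
            reasons.append("short_tracking")
        rows.append(
            {
                "participant_id": pid,
                "weekly_hours": weekly,
                "logged_fraction": logged,
                "days_tracked": days,
                "included": not reasons,
                "reasons": ";".join(reasons),
            }
        )
    report = InclusionReport(pd.DataFrame(rows))
    keep = set(report.included_ids)
    return (
        sessions[sessions["participant_id"].isin(keep)].reset_index(drop=True),
        daily[daily["participant_id"].isin(keep)].reset_index(drop=True),
        report,
    )


def _knn_impute_block(block: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Standardized k-NN imputation of one participant's diet/training block."""
    means = block.mean()
    sds = block.std(ddof=1).replace(0.0, 1.0).fillna(1.0)
    z = (block - means) / sds
    imputer = KNNImputer(n_neighbors=min(k, max(1, len(block) - 1)))
    filled = pd.DataFrame(imputer.fit_transform(z), columns=block.columns, index=block.index)
    return filled * sds + means


def impute_missing(daily: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Impute raw daily-log gaps within each participant.

    The calendar is first completed (days dropped as incomplete reappear as
    fully missing rows so rolling windows stay gap-free).  Diet columns are
    filled by k-nearest-neighbour on the standardized within-participant
    block (mean fallback when no neighbour is defined); all other predictor
    columns use the participant median.  Current-day outcome readings
    (AM PRS, Ln rMSSD) are left untouched unless missing, in which case they
    are median-filled only for use as lagged predictors downstream.
    """
    out_parts = []
    value_cols = [c for c in daily.columns if c not in ("participant_id", "date")]
    for pid, g in daily.groupby("participant_id", sort=True):
        g = g.sort_values("date").reset_index(drop=True)
        dates = pd.to_datetime(g["date"])
        full = pd.date_range(dates.min(), dates.max(), freq="D")
        g = (
            g.set_index(dates)
            .drop(columns=["date"])
            .reindex(full)
            .assign(participant_id=pid)
            .reset_index()
            .rename(columns={"index": "date"})
        )
        g["date"] = g["date"].dt.date.astype(str)
        all_missing = [c for c in value_cols if g[c].isna().all()]
        if all_missing:
            raise ValueError(
                f"participant {pid}: columns entirely missing: {all_missing}"
            )
        diet_cols = [c for c in DIET_TRAINING_COLUMNS if c in g.columns]
        if diet_cols and g[diet_cols].isna().to_numpy().any():
            g[diet_cols] = _knn_impute_block(g[diet_cols], k=k)
        for c in value_cols:
            if c in diet_cols:
                continue
            if g[c].isna().any():
                g[c] = g[c].fillna(g[c].median())
        out_parts.append(g)
    return pd.concat(out_parts, ignore_index=True)[daily.columns]


def impute_features(
    table: pd.DataFrame, manifest: list[ColumnSpec]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median-fill residual derived-feature gaps (warm-up windows, zero-SD
    monotony) within participant.

    Returns the filled table plus the original missingness mask of the
    outcome columns, so unfolding can drop rows whose lag-0 outcome was not
    actually observed.
    """
    table = table.copy()
    outcome_missing = table[list(OUTCOME_COLUMNS)].isna()
    feature_cols = [c.name for c in manifest]
    for pid, idx in table.groupby("participant_id", sort=False).groups.items():
        sub = table.loc[idx, feature_cols]
        med = sub.median(numeric_only=True)
        table.loc[idx, feature_cols] = sub.fillna(med)
    still = table[feature_cols].isna().any()
    if still.any():
        # column all-missing for some participant: fall back to cohort median
        for c in still[still].index:
            table[c] = table[c].fillna(table[c].median())
    return table, outcome_missing


def prune_correlated(
    X: pd.DataFrame, threshold: float = 0.85
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Iteratively drop one member of every |r| > threshold predictor pair.

    At each step the most correlated pair is found and the member with the
    larger mean absolute correlation against all remaining columns is
    removed; correlations are then recomputed.  Constant columns are dropped
    first (correlation undefined).  Returns the pruned matrix and a list of
    (column, reason) removals.
    """
    removed: list[tuple[str, str]] = []
    X = X.copy()
    sds = X.std(ddof=1)
    for c in X.columns[(sds == 0) | sds.isna()]:
        removed.append((c, "zero_variance"))
    X = X.drop(columns=[c for c, _ in removed])
    if X.shape[1] < 2:
        return X, removed
    corr = X.corr().to_numpy()
    cols = list(X.columns)
    np.fill_diagonal(corr, 0.0)
    corr = np.abs(corr)
    while True:
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] <= threshold:
            break
        mean_i = corr[i].sum() / (corr.shape[0] - 1)
        mean_j = corr[j].sum() / (corr.shape[0] - 1)
        drop = i if mean_i >= mean_j else j
        removed.append((cols[drop], f"correlated_with:{cols[j if drop == i else i]}"))
        corr = np.delete(np.delete(corr, drop, axis=0), drop, axis=1)
        del cols[drop]
        if corr.shape[0] < 2:
            break
    return X[cols], removed


def markov_unfold(
    table: pd.DataFrame,
    manifest: list[ColumnSpec],
    outcome: str,
    n_lags: int = 7,
    same_day_policy: str = "morning_only",
    outcome_missing: pd.DataFrame | None = None,
) -> UnfoldedDataset:
    """Unfold the feature table into an independent-observation design matrix.

    Performed independently per participant: dynamic columns are stacked at
    lags 0..n (lag-0 admission governed by the leakage policy), static
    subject characteristics pass through unlagged, and the first ``n_lags``
    rows of each participant are discarded.  Participants with fewer than
    ``n_lags + 1`` rows are dropped with a warning.
    """
    if outcome not in OUTCOME_TO_COLUMN:
        raise ValueError(f"unknown outcome {outcome!r}")
    outcome_col = OUTCOME_TO_COLUMN[outcome]
    out_family = _OUTCOME_FAMILY[outcome_col]
    dynamic = [c for c in manifest if c.dynamic]
    static = [c for c in manifest if not c.dynamic]

    X_parts, y_parts, g_parts = [], [], []
    for pid, g in table.groupby("participant_id", sort=True):
        g = g.sort_values("date")
        orig_idx = g.index
        g = g.reset_index(drop=True)
        if len(g) <= n_lags:
            warnings.warn(f"participant {pid}: only {len(g)} rows, dropped from unfolding")
            continue
        cols = {}
        for spec in dynamic:
            series = g[spec.name].to_numpy(float)
            lag0_ok = (
                spec.name != outcome_col
                and spec.family not in out_family
                and (spec.morning or same_day_policy == "all_lag0")
            )
            if lag0_ok:
                cols[spec.name] = series
            for k in range(1, n_lags + 1):
                shifted = np.empty_like(series)
                shifted[:k] = np.nan
                shifted[k:] = series[:-k] if k else series
                cols[f"{spec.name}__lag{k}"] = shifted
        for spec in static:
            cols[spec.name] = g[spec.name].to_numpy(float)
        Xp = pd.DataFrame(cols).iloc[n_lags:].reset_index(drop=True)
        yp = g[outcome_col].iloc[n_lags:].reset_index(drop=True).astype(float)
        if outcome_missing is not None:
            miss = outcome_missing.loc[orig_idx, outcome_col].iloc[n_lags:].reset_index(drop=True)
            keepmask = ~miss.to_numpy()
            Xp, yp = Xp.loc[keepmask].reset_index(drop=True), yp.loc[keepmask].reset_index(drop=True)
        keep = yp.notna().to_numpy()
        Xp, yp = Xp.loc[keep], yp.loc[keep]
        X_parts.append(Xp)
        y_parts.append(yp)
        g_parts.extend([pid] * len(yp))
    if not X_parts:
        raise EmptyCohortError("no participant has enough rows to unfold")
    X = pd.concat(X_parts, ignore_index=True)
    y = pd.concat(y_parts, ignore_index=True).rename(outcome)
    public = "am_prs" if outcome_col == "am_prs_c" else outcome_col
    return UnfoldedDataset(
        X=X,
        y=y,
        groups=pd.Series(g_parts, name="participant_id"),
        outcome=public,
        manifest=manifest,
        n_lags=n_lags,
    )


def select_variable_set(
    ds: UnfoldedDataset,
    set_name: str,
    top5: list[str] | None = None,
    include_interactions: bool = False,
) -> UnfoldedDataset:
    """Restrict the design matrix to a named variable set.

    ``MAIN`` keeps every monitoring variable; ``ACTIONABLE`` keeps only
    variables an athlete or coach can directly manipulate (training, diet,
    sleep duration) — no column derived from PRS, HRV, resting HR, sleep
    quality, or sleep index survives; ``TOP5`` keeps an explicit list of
    unfolded column names.  Planned interaction columns are admitted only on
    request (they serve the interaction-aware learner).
    """
    by_name = {c.name: c for c in ds.manifest}
    if set_name == "TOP5":
        if not top5:
            raise ValueError("TOP5 requires an explicit feature list")
        missing = [c for c in top5 if c not in ds.X.columns]
        if missing:
            raise ValueError(f"TOP5 columns not in design matrix: {missing}")
        keep = list(top5)
    elif set_name in ("MAIN", "ACTIONABLE"):
        keep = []
        for col in ds.X.columns:
            spec = by_name[ds.base_of(col)]
            if spec.family == "interaction":
                if include_interactions and spec.interaction_for == ds.outcome:
                    keep.append(col)
                continue
            if set_name == "MAIN" and spec.main:
                keep.append(col)
            elif set_name == "ACTIONABLE" and spec.main and spec.actionable:
                keep.append(col)
    else:
        raise ValueError(f"unknown variable set {set_name!r}")
    return replace(ds, X=ds.X[keep])
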