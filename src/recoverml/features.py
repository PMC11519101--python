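"""Per-day feature engineering from raw session and daily logs.

Produces one row per participant-day with the full monitoring variable set:
session-RPE training load and its 7-day rolling summaries (monotony, strain,
EWMA, moving average, 7-day max), diet dailies with 3- and 7-day means and
carbohydrate monotony, sleep index, wellness scores, participant-centered
AM PRS, HRV / resting-HR dailies with day-to-day changes and 7-day
(exponentially) weighted averages, day-of-week indicators, and the planned
interaction columns.  A machine-readable column manifest tags each variable
with its variable-set membership (MAIN / ACTIONABLE), morning availability,
and family (used downstream for leakage-safe lag policies).

Conventions: rolling windows are trailing and include the current day; a
rolling value is only emitted once its full window is available (warm-up
days are missing, not zero-filled); SDs are sample (n-1) SDs; the 7-day EWMA
uses the span-7 smoothing constant alpha = 2/(7+1) seeded at the first
observation; monotony with a zero SD window is missing rather than infinite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ColumnSpec",
    "session_load",
    "aggregate_daily",
    "rolling_load_metrics",
    "rolling_diet_metrics",
    "sleep_index",
    "hrv_change",
    "center_by_participant",
    "consecutive_training_days",
    "build_feature_table",
    "OUTCOME_COLUMNS",
]

EWMA_SPAN = 7
WINDOW = 7

OUTCOME_COLUMNS = ("am_prs_c", "hrv_change")


class SchemaError(ValueError):
    """Raised when a raw log table is missing required columns."""


@dataclass
class ColumnSpec:
    """Manifest entry for one feature column."""

    name: str
    family: str  # training | diet | sleep | wellness | prs | hrv | hr | calendar | interaction | static
    morning: bool  # known at the morning observation of day t
    main: bool = True
    actionable: bool = True
    interaction_for: str | None = None  # outcome this planned interaction serves
    parents: tuple[str, ...] = ()
    dynamic: bool = True
    units: str = ""


def _manifest() -> list[ColumnSpec]:
    cols: list[ColumnSpec] = []

    def add(name, family, morning, actionable=True, main=True, **kw):
        cols.append(ColumnSpec(name, family, morning, main, actionable, **kw))

    # training (post-morning on day t)
    for name, units in [
        ("duration_min", "min"),
        ("tl", "AU"),
        ("srpe_max", "CR100"),
        ("srpe_wmean", "CR100"),
        ("n_workouts", "count"),
        ("consec_days", "days"),
        ("fasted", "flag"),
        ("mod_swim", "flag"),
        ("mod_bike", "flag"),
        ("mod_run", "flag"),
        ("mod_strength", "flag"),
        ("mod_other", "flag"),
        ("monotony7", "ratio"),
        ("strain7", "AU"),
        ("ewma_tl", "AU"),
        ("ma7_tl", "AU"),
        ("max_tl7", "AU"),
    ]:
        add(name, "training", morning=False, units=units)
    # diet (post-morning)
    for name in [
        "kcal",
        "cho_g_kg",
        "fat_g_kg",
        "protein_g_kg",
        "pre_ex_cho_g",
        "ma3_cho",
        "ma3_fat",
        "ma3_protein",
        "ma3_kcal",
        "ma7_cho",
        "ma7_fat",
        "ma7_protein",
        "ma7_kcal",
        "sd7_cho",
        "cho_monotony7",
    ]:
        add(name, "diet", morning=False)
    # sleep (morning-available); index and quality are monitoring readouts,
    # not directly actionable
    add("sleep_h", "sleep", morning=True, units="h")
    add("sleep_index", "sleep", morning=True, actionable=False, units="h*points")
    add("ma7_sleep_h", "sleep", morning=True, units="h")
    add("ma7_sleep_index", "sleep", morning=True, actionable=False, units="h*points")
    # wellness
    add("soreness", "wellness", morning=True, units="1-10")
    add("life_stress", "wellness", morning=True, units="1-7")
    add("sleep_quality", "wellness", morning=True, actionable=False, units="1-7")
    # centered PRS (outcome; lags usable as predictors, never actionable)
    add("am_prs_c", "prs", morning=True, actionable=False, units="points")
    # HRV / HR readouts (never actionable)
    for name in ["ln_rmssd", "hrv_change", "ma7_hrv", "ewma_hrv"]:
        add(name, "hrv", morning=True, actionable=False, units="Ln rMSSD")
    for name in ["resting_hr", "hr_change", "ma7_hr", "ewma_hr"]:
        add(name, "hr", morning=True, actionable=False, units="bpm")
    # calendar
    for d in ["mon", "tue", "wed", "thu", "fri", "sat", "sun"]:
        add(f"dow_{d}", "calendar", morning=True, units="flag")
    # planned interactions (entered only by the interaction-aware learner)
    cols.append(
        ColumnSpec(
            "ix_tl7_cho3", "interaction", morning=False, main=False, actionable=False,
            interaction_for="am_prs", parents=("ma7_tl", "ma3_cho"),
        )
    )
    cols.append(
        ColumnSpec(
            "ix_mono7_cho3", "interaction", morning=False, main=False, actionable=False,
            interaction_for="am_prs", parents=("monotony7", "ma3_cho"),
        )
    )
    cols.append(
        ColumnSpec(
            "ix_tl1_sleep", "interaction", morning=True, main=False, actionable=False,
            interaction_for="hrv_change", parents=("tl__lag1", "sleep_h"),
        )
    )
    cols.append(
        ColumnSpec(
            "ix_tl1_prs1", "interaction", morning=True, main=False, actionable=False,
            interaction_for="hrv_change", parents=("tl__lag1", "am_prs_c__lag1"),
        )
    )
    # static subject characteristics
    cols.append(
        ColumnSpec("body_mass_kg", "static", morning=True, dynamic=False, units="kg")
    )
    return cols


def session_load(duration_min: float, rpe: float) -> float:
    """Session training load: RPE (CR100) x duration in minutes / 10."""
    if duration_min <= 0:
        raise ValueError("duration_min must be > 0")
    if not 0 <= rpe <= 100:
        raise ValueError("rpe must be within [0, 100]")
    return duration_min * rpe / 10.0


def aggregate_daily(sessions: pd.DataFrame) -> dict[str, float]:
    """Collapse one participant-day's sessions into daily training fields.

    An empty session list is a rest day (zeros/False), not an error.
    Multi-session days use the duration-weighted mean for daily sRPE and
    pre-exercise carbohydrate; the fasted flag is true if any session was
    fasted (< 5 g CHO in the pre-exercise window).
    """
    out = {
        "duration_min": 0.0,
        "tl": 0.0,
        "srpe_max": 0.0,
        "srpe_wmean": 0.0,
        "n_workouts": 0,
        "pre_ex_cho_g": 0.0,
        "fasted": 0,
        **{f"mod_{m}": 0 for m in ("swim", "bike", "run", "strength", "other")},
    }
    if len(sessions) == 0:
        return out
    if sessions["participant_id"].nunique() > 1 or sessions["date"].nunique() > 1:
        raise ValueError("aggregate_daily expects sessions of one participant-day")
    dur = sessions["duration_min"].to_numpy(float)
    rpe = sessions["rpe"].to_numpy(float)
    cho = sessions["pre_ex_cho_g"].to_numpy(float)
    out["duration_min"] = float(dur.sum())
    out["tl"] = float(np.sum(dur * rpe / 10.0))
    out["srpe_max"] = float(rpe.max())
    out["srpe_wmean"] = float(np.sum(rpe * dur) / dur.sum())
    out["n_workouts"] = int(len(sessions))
    out["pre_ex_cho_g"] = float(np.sum(cho * dur) / dur.sum())
    out["fasted"] = int(bool((cho < 5.0).any()))
    for m in sessions["modality"]:
        key = f"mod_{m}" if f"mod_{m}" in out else "mod_other"
        out[key] = 1
    return out


def _check_series(dates: pd.Series | None) -> None:
    if dates is None:
        return
    d = pd.to_datetime(dates)
    if not d.is_monotonic_increasing:
        raise ValueError("dates must be chronologically sorted")
    gaps = d.diff().dropna()
    if len(gaps) and (gaps != pd.Timedelta(days=1)).any():
        raise ValueError("dates must be calendar-complete (no gaps)")


def rolling_load_metrics(
    tl: pd.Series, window: int = WINDOW, dates: pd.Series | None = None
) -> pd.DataFrame:
    """7-day monotony, strain, EWMA, moving average and max of daily load.

    The series must be one participant's calendar-complete days with rest
    days recorded as zero load.  Monotony is the window mean over the sample
    SD; a zero-SD window yields a missing monotony (and strain) rather than
    an infinity.  The EWMA is seeded at the first value with alpha = 2/(span+1).
    """
    _check_series(dates)
    tl = pd.Series(np.asarray(tl, dtype=float))
    roll = tl.rolling(window, min_periods=window)
    mean = roll.mean()
    sd = roll.std(ddof=1)
    monotony = mean / sd.replace(0.0, np.nan)
    total = roll.sum()
    strain = total * monotony
    ewma = tl.ewm(span=EWMA_SPAN, adjust=False).mean()
    return pd.DataFrame(
        {
            "monotony7": monotony,
            "strain7": strain,
            "ewma_tl": ewma,
            "ma7_tl": mean,
            "max_tl7": roll.max(),
        }
    )


def rolling_diet_metrics(diet: pd.DataFrame, dates: pd.Series | None = None) -> pd.DataFrame:
    """3-/7-day trailing means of CHO, fat, protein, kcal plus CHO variability."""
    _check_series(dates)
    need = ["cho_g_kg", "fat_g_kg", "protein_g_kg", "kcal"]
    missing = [c for c in need if c not in diet.columns]
    if missing:
        raise SchemaError(f"diet table missing columns: {missing}")
    out = {}
    short = {"cho_g_kg": "cho", "fat_g_kg": "fat", "protein_g_kg": "protein", "kcal": "kcal"}
    for col, tag in short.items():
        s = pd.Series(diet[col].to_numpy(float))
        out[f"ma3_{tag}"] = s.rolling(3, min_periods=3).mean()
        out[f"ma7_{tag}"] = s.rolling(WINDOW, min_periods=WINDOW).mean()
    cho = pd.Series(diet["cho_g_kg"].to_numpy(float))
    sd7 = cho.rolling(WINDOW, min_periods=WINDOW).std(ddof=1)
    out["sd7_cho"] = sd7
    out["cho_monotony7"] = cho.rolling(WINDOW, min_periods=WINDOW).mean() / sd7.replace(0.0, np.nan)
    return pd.DataFrame(out)


def sleep_index(sleep_h: float | np.ndarray, sleep_quality: float | np.ndarray) -> float | np.ndarray:
    """Sleep index = sleep duration (h) x subjective quality (1-7)."""
    q = np.asarray(sleep_quality, dtype=float)
    valid = np.isnan(q) | ((q >= 1) & (q <= 7))
    if not np.all(valid):
        raise ValueError("sleep_quality must be within [1, 7]")
    result = np.asarray(sleep_h, dtype=float) * q
    return float(result) if result.ndim == 0 else result


def hrv_change(ln_rmssd: pd.Series, dates: pd.Series | None = None) -> pd.Series:
    """Day-over-day difference of Ln rMSSD; first day is missing."""
    _check_series(dates)
    return pd.Series(np.asarray(ln_rmssd, dtype=float)).diff()


def center_by_participant(values: pd.Series, participant_ids: pd.Series) -> pd.Series:
    """Center values around each participant's mean (missing kept missing)."""
    v = pd.Series(np.asarray(values, dtype=float))
    ids = pd.Series(np.asarray(participant_ids))
    all_missing = v.groupby(ids).apply(lambda g: g.isna().all())
    if all_missing.any():
        bad = list(all_missing[all_missing].index)
        raise ValueError(f"participants with all-missing values: {bad}")
    return v - ids.map(v.groupby(ids).mean())


def consecutive_training_days(tl: pd.Series) -> pd.Series:
    """Running count of consecutive days with nonzero training load."""
    t = np.asarray(tl, dtype=float) > 0
    out = np.zeros(len(t), dtype=int)
    run = 0
    for i, active in enumerate(t):
        run = run + 1 if active else 0
        out[i] = run
    return pd.Series(out)


def _daily_training_table(sessions: pd.DataFrame, daily_index: pd.DataFrame) -> pd.DataFrame:
    """Vectorized per-day aggregation of the sessions table."""
    base = daily_index[["participant_id", "date"]].copy()
    if len(sessions) == 0:
        agg = pd.DataFrame(columns=["participant_id", "date"])
    else:
        s = sessions.copy()
        s["load"] = s["duration_min"].to_numpy(float) * s["rpe"].to_numpy(float) / 10.0
        s["rpe_x_dur"] = s["rpe"] * s["duration_min"]
        s["cho_x_dur"] = s["pre_ex_cho_g"] * s["duration_min"]
        s["is_fasted"] = (s["pre_ex_cho_g"] < 5.0).astype(int)
        for m in ("swim", "bike", "run", "strength", "other"):
            s[f"mod_{m}"] = (s["modality"] == m).astype(int)
        grouped = s.groupby(["participant_id", "date"], sort=False)
        agg = grouped.agg(
            duration_min=("duration_min", "sum"),
            tl=("load", "sum"),
            srpe_max=("rpe", "max"),
            n_workouts=("rpe", "size"),
            rpe_x_dur=("rpe_x_dur", "sum"),
            cho_x_dur=("cho_x_dur", "sum"),
            fasted=("is_fasted", "max"),
            mod_swim=("mod_swim", "max"),
            mod_bike=("mod_bike", "max"),
            mod_run=("mod_run", "max"),
            mod_strength=("mod_strength", "max"),
            mod_other=("mod_other", "max"),
        ).reset_index()
        agg["srpe_wmean"] = agg["rpe_x_dur"] / agg["duration_min"]
        agg["pre_ex_cho_g"] = agg["cho_x_dur"] / agg["duration_min"]
        agg = agg.drop(columns=["rpe_x_dur", "cho_x_dur"])
    out = base.merge(agg, on=["participant_id", "date"], how="left")
    fill_cols = [
        "duration_min", "tl", "srpe_max", "srpe_wmean", "n_workouts",
        "pre_ex_cho_g", "fasted", "mod_swim", "mod_bike", "mod_run",
        "mod_strength", "mod_other",
    ]
    out[fill_cols] = out[fill_cols].fillna(0.0)
    return out


def build_feature_table(
    sessions: pd.DataFrame,
    daily: pd.DataFrame,
    training_feeling: pd.Series | None = None,
) -> tuple[pd.DataFrame, list[ColumnSpec]]:
    """Assemble the full feature table plus its column manifest.

    One row per participant-day; rolling columns are missing during each
    participant's warm-up window.  ``training_feeling`` is an optional
    pass-through column aligned with ``daily``.
    """
    required = [
        "participant_id", "date", "kcal", "cho_g_kg", "fat_g_kg", "protein_g_kg",
        "sleep_h", "sleep_quality", "soreness", "life_stress", "am_prs",
        "ln_rmssd", "resting_hr", "body_mass_kg",
    ]
    missing = [c for c in required if c not in daily.columns]
    if missing:
        raise SchemaError(f"daily table missing required columns: {missing}")
    for c in ["participant_id", "date", "modality", "duration_min", "rpe", "pre_ex_cho_g"]:
        if c not in sessions.columns:
            raise SchemaError(f"sessions table missing required column: {c}")

    daily = daily.sort_values(["participant_id", "date"]).reset_index(drop=True)
    dup = daily.duplicated(["participant_id", "date"])
    if dup.any():
        raise SchemaError("daily table has duplicate participant-date rows")

    feat = _daily_training_table(sessions, daily)
    parts = []
    for pid, g in daily.groupby("participant_id", sort=False):
        g = g.reset_index(drop=True)
        tr = feat[feat["participant_id"] == pid].reset_index(drop=True)
        _check_series(g["date"])
        block = pd.concat(
            [
                tr,
                rolling_load_metrics(tr["tl"]),
                rolling_diet_metrics(g),
            ],
            axis=1,
        )
        block["consec_days"] = consecutive_training_days(tr["tl"]).to_numpy()
        for c in ["kcal", "cho_g_kg", "fat_g_kg", "protein_g_kg", "sleep_h",
                  "sleep_quality", "soreness", "life_stress", "am_prs",
                  "ln_rmssd", "resting_hr", "body_mass_kg"]:
            block[c] = g[c].to_numpy()
        block["sleep_index"] = block["sleep_h"].to_numpy(float) * block["sleep_quality"].to_numpy(float)
        block["ma7_sleep_h"] = pd.Series(block["sleep_h"].to_numpy(float)).rolling(WINDOW, min_periods=WINDOW).mean().to_numpy()
        block["ma7_sleep_index"] = pd.Series(block["sleep_index"].to_numpy(float)).rolling(WINDOW, min_periods=WINDOW).mean().to_numpy()
        hrv = pd.Series(block["ln_rmssd"].to_numpy(float))
        block["hrv_change"] = hrv.diff().to_numpy()
        block["ma7_hrv"] = hrv.rolling(WINDOW, min_periods=WINDOW).mean().to_numpy()
        block["ewma_hrv"] = hrv.ewm(span=EWMA_SPAN, adjust=False).mean().to_numpy()
        hr = pd.Series(block["resting_hr"].to_numpy(float))
        block["hr_change"] = hr.diff().to_numpy()
        block["ma7_hr"] = hr.rolling(WINDOW, min_periods=WINDOW).mean().to_numpy()
        block["ewma_hr"] = hr.ewm(span=EWMA_SPAN, adjust=False).mean().to_numpy()
        # planned interactions referencing prior-day values
        tl_lag1 = pd.Series(block["tl"].to_numpy(float)).shift(1)
        block["ix_tl1_sleep"] = (tl_lag1 * block["sleep_h"].to_numpy(float)).to_numpy()
        parts.append(block)
    table = pd.concat(parts, ignore_index=True)

    table["am_prs_c"] = center_by_participant(table["am_prs"], table["participant_id"]).to_numpy()
    table = table.drop(columns=["am_prs"])
    prs_lag1 = table.groupby("participant_id")["am_prs_c"].shift(1)
    tl_lag1_all = table.groupby("participant_id")["tl"].shift(1)
    table["ix_tl1_prs1"] = (tl_lag1_all * prs_lag1).to_numpy()
    table["ix_tl7_cho3"] = table["ma7_tl"] * table["ma3_cho"]
    table["ix_mono7_cho3"] = table["monotony7"] * table["ma3_cho"]

    dow = pd.to_datetime(table["date"]).dt.weekday
    for i, d in enumerate(["mon", "tue", "wed", "thu", "fri", "sat", "sun"]):
        table[f"dow_{d}"] = (dow == i).astype(int)

    manifest = _manifest()
    if training_feeling is not None:
        table["training_feeling"] = np.asarray(training_feeling, dtype=float)
        manifest.append(
            ColumnSpec("training_feeling", "wellness", morning=True, units="AU")
        )
    ordered = ["participant_id", "date"] + [c.name for c in manifest]
    return table[ordered], manifest
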