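"""Synthetic multi-athlete daily-log generator with known ground truth.

Emulates a 12-week observational monitoring study of endurance athletes:
every athlete logs workouts (modality, duration, CR100 RPE, pre-exercise
carbohydrate), daily diet totals, sleep, morning wellness scores, morning
perceived recovery status (AM PRS, 0-100), and Ln rMSSD heart-rate
variability.  The two outcomes are generated from known coefficient vectors
so downstream feature engineering, model fitting and importance rankings can
be validated by parameter recovery:

* Ln rMSSD follows a mean-reverting AR(1) around a personal baseline,
  ``x_t = mu_i + phi_i (x_{t-1} - mu_i) + gamma * load_{t-1} + delta *
  sleep_t + eps_t``, so the day-to-day change regresses negatively on the
  previous level (the closed-form lag-1 autocorrelation of the change is
  ``(phi - 1) / 2`` for the pure AR(1) core).
* AM PRS is the personal mean plus an AR(1) carry-over of the centered
  previous score plus linear effects of standardized wellness/behaviour
  drivers plus Gaussian noise, clipped to [0, 100].

Wellness integers are binned latent Gaussians driven by recent load and
sleep; training follows a weekly cycle with long weekend sessions; diet
totals track training load.  Missingness is MCAR over predictor columns
only (current-day outcomes are never blanked).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import (
    ConfigurationError,
    GeneratorConfig,
    HETEROGENEITY_POOL,
)

__all__ = [
    "AthleteProfile",
    "GroundTruth",
    "generate_cohort",
    "simulate_outcomes",
    "apply_missingness",
    "write_cohort",
]

MODALITIES = ("swim", "bike", "run", "strength", "other")

#: Daily-table columns eligible for MCAR blanking (predictors only; the
#: current day's outcome readings are always retained).
ELIGIBLE_MISSING_COLUMNS = (
    "kcal",
    "cho_g_kg",
    "fat_g_kg",
    "protein_g_kg",
    "sleep_h",
    "sleep_quality",
    "soreness",
    "life_stress",
    "resting_hr",
    "body_mass_kg",
)

# Within-athlete day-to-day SDs used both to draw daily values and to
# standardize the latent drivers entering the PRS model.
_WITHIN_SD = {
    "sleep_h": 0.55,
    "cho_g_kg": 0.70,
    "protein_g_kg": 0.30,
    "fat_g_kg": 0.40,
}


@dataclass
class AthleteProfile:
    """Per-athlete generative parameters (the simulation's ground truth)."""

    participant_id: str
    weekly_hours: float
    prs_mean: float
    hrv_baseline: float
    hrv_phi: float
    personal_betas: dict[str, float]
    diet_means: dict[str, float]  # kcal_kg, cho_g_kg, fat_g_kg, protein_g_kg
    sleep_mean_h: float
    body_mass_kg: float
    hr_baseline: float
    sport: str = "triathlon"

    def validate(self) -> None:
        if not 3.0 <= self.hrv_baseline <= 5.0:
            raise ConfigurationError("hrv_baseline outside [3, 5]")
        if not 0.0 < self.hrv_phi < 1.0:
            raise ConfigurationError("hrv_phi outside (0, 1)")
        if self.weekly_hours <= 0:
            raise ConfigurationError("weekly_hours must be > 0")


@dataclass
class GroundTruth:
    """Everything needed to check parameter/importance recovery downstream."""

    profiles: list[AthleteProfile]
    effect_sizes: dict[str, float]
    true_features: dict[str, list[str]] = field(default_factory=dict)
    config: dict | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "effect_sizes": self.effect_sizes,
            "true_features": self.true_features,
            "profiles": [asdict(p) for p in self.profiles],
            "config": self.config,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=float))


# Driver key -> unfolded predictor column carrying that signal (lag suffix
# refers to the design matrix produced by preprocessing.markov_unfold).
_PRS_DRIVER_COLUMNS = {
    "prs_soreness": "soreness",
    "prs_life_stress": "life_stress",
    "prs_sleep_quality": "sleep_quality",
    "prs_lag1": "am_prs_c__lag1",
    "prs_sleep_h": "sleep_h",
    "prs_protein": "protein_g_kg__lag1",
    "prs_cho_ma3": "ma3_cho__lag1",
    "prs_tl_lag1": "tl__lag1",
}


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(s) for s in children]


def _draw_profiles(config: GeneratorConfig, rng: np.random.Generator) -> list[AthleteProfile]:
    profiles = []
    n = config.n_participants
    sports = rng.choice(
        ["triathlon", "running", "cycling", "rowing"], size=n, p=[0.67, 0.20, 0.11, 0.02]
    )
    for i in range(n):
        betas = {k: v for k, v in config.effect_sizes.items()}
        if config.heterogeneity_sd > 0:
            for k in HETEROGENEITY_POOL:
                betas[k] = betas.get(k, 0.0) + rng.normal(0.0, config.heterogeneity_sd)
        lo, hi = config.hrv_phi_range
        cho = float(np.clip(rng.normal(4.1, 1.2), 1.5, 8.0))
        protein = float(np.clip(rng.normal(1.9, 0.35), 1.0, 3.2))
        fat = float(np.clip(rng.normal(1.7, 0.45), 0.6, 3.2))
        profiles.append(
            AthleteProfile(
                participant_id=f"P{i + 1:03d}",
                weekly_hours=float(np.clip(rng.normal(11.8, 3.3), 6.8, 22.0)),
                prs_mean=float(np.clip(rng.normal(65.0, 8.0), 40.0, 85.0)),
                hrv_baseline=float(np.clip(rng.normal(4.0, 0.35), 3.1, 4.9)),
                hrv_phi=float(rng.uniform(lo, hi)),
                personal_betas=betas,
                diet_means={
                    "cho_g_kg": cho,
                    "protein_g_kg": protein,
                    "fat_g_kg": fat,
                    "kcal_kg": 4.0 * cho + 4.0 * protein + 9.0 * fat,
                },
                sleep_mean_h=float(np.clip(rng.normal(7.5, 0.5), 6.0, 9.0)),
                body_mass_kg=float(np.clip(rng.normal(71.0, 10.0), 48.0, 100.0)),
                hr_baseline=float(np.clip(rng.normal(55.0, 6.0), 40.0, 75.0)),
                sport=str(sports[i]),
            )
        )
    return profiles


def _simulate_training(
    profile: AthleteProfile,
    dates: pd.DatetimeIndex,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> tuple[list[dict], np.ndarray]:
    """Sessions for one athlete plus the daily training-load vector."""
    wp = config.weekly_pattern
    p = np.asarray(wp.train_prob)
    m = np.asarray(wp.volume_mult)
    # base minutes chosen so E[weekly minutes] = weekly_hours * 60
    base = profile.weekly_hours * 60.0 / float((p * m).sum())
    mod_weights = {
        "triathlon": [0.2, 0.4, 0.3, 0.07, 0.03],
        "running": [0.0, 0.05, 0.8, 0.1, 0.05],
        "cycling": [0.0, 0.85, 0.03, 0.09, 0.03],
        "rowing": [0.05, 0.1, 0.1, 0.15, 0.6],
    }[profile.sport]
    sessions: list[dict] = []
    tl = np.zeros(len(dates))
    for t, date in enumerate(dates):
        wd = date.weekday()
        if rng.random() >= p[wd]:
            continue
        target = base * m[wd]
        total_min = float(np.clip(rng.lognormal(np.log(target) - 0.35**2 / 2, 0.35), 20, 400))
        two = rng.random() < (0.30 if total_min > 90 else 0.08)
        if two:
            frac = rng.uniform(0.3, 0.5)
            durations = [total_min * (1 - frac), total_min * frac]
        else:
            durations = [total_min]
        for dur in durations:
            dur = max(15.0, round(dur))
            rpe = float(np.clip(round(rng.normal(45.0, 13.0) - 0.04 * (dur - 90.0)), 10, 95))
            fasted = rng.random() < 0.30
            if fasted:
                cho_pre = float(np.round(rng.uniform(0.0, 4.5), 1))
            else:
                cho_pre = float(np.round(np.clip(rng.lognormal(np.log(38.0), 0.55), 5.0, 150.0), 1))
            modality = str(rng.choice(MODALITIES, p=mod_weights))
            sessions.append(
                {
                    "participant_id": profile.participant_id,
                    "date": date.date().isoformat(),
                    "modality": modality,
                    "duration_min": dur,
                    "rpe": rpe,
                    "pre_ex_cho_g": cho_pre,
                }
            )
            tl[t] += dur * rpe / 10.0
    return sessions, tl


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def simulate_outcomes(
    profiles: Sequence[AthleteProfile],
    covariates: pd.DataFrame,
    *,
    noise_sd_prs: float,
    hrv_noise_sd: float,
    rngs: Sequence[np.random.Generator] | None = None,
    hrv_init: dict[str, float] | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Generate (am_prs, ln_rmssd) for pre-simulated covariate series.

    ``covariates`` is a long table with ``participant_id`` plus the
    standardized driver columns ``z_soreness``, ``z_life_stress``,
    ``z_sleep_quality``, ``z_sleep_h``, ``z_protein``, ``z_cho_ma3``,
    ``z_tl_lag1`` and the raw helpers ``tl_centered_lag1`` and
    ``sleep_dev`` (hours above the athlete's mean), one row per day in
    chronological order.  Rows of each participant must be contiguous.
    ``hrv_init`` optionally pins a participant's pre-series HRV state
    x_0 (defaults to a stationary draw, or the baseline when noise-free).
    """
    required = [
        "participant_id",
        "z_soreness",
        "z_life_stress",
        "z_sleep_quality",
        "z_sleep_h",
        "z_protein",
        "z_cho_ma3",
        "z_tl_lag1",
        "tl_centered_lag1",
        "sleep_dev",
    ]
    missing = [c for c in required if c not in covariates.columns]
    if missing:
        raise ValueError(f"covariate table missing columns: {missing}")
    by_id = {p.participant_id: p for p in profiles}
    counts = covariates["participant_id"].value_counts()
    unknown = set(counts.index) - set(by_id)
    if unknown:
        raise ValueError(f"covariates reference unknown participants: {sorted(unknown)}")
    if len(set(counts)) > 1:
        raise ValueError("covariate series have unequal lengths across participants")
    if rngs is None:
        rngs = [np.random.default_rng(0) for _ in profiles]

    prs_out = np.empty(len(covariates))
    hrv_out = np.empty(len(covariates))
    for profile, rng in zip(profiles, rngs):
        mask = (covariates["participant_id"] == profile.participant_id).to_numpy()
        sub = covariates.loc[mask]
        T = len(sub)
        b = profile.personal_betas
        drift = (
            b.get("prs_soreness", 0.0) * sub["z_soreness"].to_numpy()
            + b.get("prs_life_stress", 0.0) * sub["z_life_stress"].to_numpy()
            + b.get("prs_sleep_quality", 0.0) * sub["z_sleep_quality"].to_numpy()
            + b.get("prs_sleep_h", 0.0) * sub["z_sleep_h"].to_numpy()
            + b.get("prs_protein", 0.0) * sub["z_protein"].to_numpy()
            + b.get("prs_cho_ma3", 0.0) * sub["z_cho_ma3"].to_numpy()
            + b.get("prs_tl_lag1", 0.0) * sub["z_tl_lag1"].to_numpy()
        )
        rho = b.get("prs_lag1", 0.0)
        gamma = b.get("hrv_load_lag1", 0.0)
        delta = b.get("hrv_sleep", 0.0)
        tl_c = sub["tl_centered_lag1"].to_numpy()
        sleep_dev = sub["sleep_dev"].to_numpy()

        prs = np.empty(T)
        hrv = np.empty(T)
        prs_prev = profile.prs_mean
        mu, phi = profile.hrv_baseline, profile.hrv_phi
        if hrv_init and profile.participant_id in hrv_init:
            hrv_prev = hrv_init[profile.participant_id]
        elif hrv_noise_sd > 0:
            hrv_prev = mu + rng.normal(0.0, hrv_noise_sd / np.sqrt(1.0 - phi**2))
        else:
            hrv_prev = mu
        eps_prs = rng.normal(0.0, noise_sd_prs, T) if noise_sd_prs > 0 else np.zeros(T)
        eps_hrv = rng.normal(0.0, hrv_noise_sd, T) if hrv_noise_sd > 0 else np.zeros(T)
        for t in range(T):
            val = profile.prs_mean + rho * (prs_prev - profile.prs_mean) + drift[t] + eps_prs[t]
            prs[t] = float(np.clip(val, 0.0, 100.0))
            prs_prev = prs[t]
            hrv[t] = mu + phi * (hrv_prev - mu) + gamma * tl_c[t] + delta * sleep_dev[t] + eps_hrv[t]
            hrv_prev = hrv[t]
        prs_out[mask] = prs
        hrv_out[mask] = hrv
    idx = covariates.index
    return pd.Series(prs_out, index=idx, name="am_prs"), pd.Series(
        hrv_out, index=idx, name="ln_rmssd"
    )


def generate_cohort(
    config: GeneratorConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate the full cohort; returns (sessions, daily, ground truth).

    Deterministic for a given config (``config.seed`` is the only entropy
    source).  The daily table has exactly one row per participant-day before
    missingness; the sessions table has rows on training days only.
    """
    config = config or GeneratorConfig()
    config.validate()
    master = np.random.default_rng(np.random.SeedSequence([config.seed, 77]))
    profiles = _draw_profiles(config, master)
    rngs = _spawn_rngs(config.seed, 2 * config.n_participants + 1)
    outcome_rngs = rngs[config.n_participants : 2 * config.n_participants]
    miss_seed = int(rngs[-1].integers(0, 2**31 - 1))

    dates = pd.date_range(config.start_date, periods=config.n_days, freq="D")
    all_sessions: list[dict] = []
    daily_parts: list[pd.DataFrame] = []
    cov_parts: list[pd.DataFrame] = []
    for profile, rng in zip(profiles, rngs[: config.n_participants]):
        sessions, tl = _simulate_training(profile, dates, config, rng)
        all_sessions.extend(sessions)
        T = len(dates)

        # diet follows training load (athletes eat more on big days)
        tl_c = tl - tl.mean()
        cho = profile.diet_means["cho_g_kg"] + 0.0009 * tl_c + rng.normal(0, _WITHIN_SD["cho_g_kg"], T)
        cho = np.clip(cho, 0.5, None)
        protein = np.clip(
            profile.diet_means["protein_g_kg"] + rng.normal(0, _WITHIN_SD["protein_g_kg"], T), 0.5, None
        )
        fat = np.clip(
            profile.diet_means["fat_g_kg"] + rng.normal(0, _WITHIN_SD["fat_g_kg"], T), 0.3, None
        )
        kcal_kg = 4.0 * cho + 4.0 * protein + 9.0 * fat + rng.normal(0, 1.5, T)
        mass = profile.body_mass_kg + np.cumsum(rng.normal(0, 0.05, T))

        sleep = np.clip(profile.sleep_mean_h + rng.normal(0, _WITHIN_SD["sleep_h"], T), 4.0, 11.0)
        z_sleep = (sleep - profile.sleep_mean_h) / _WITHIN_SD["sleep_h"]
        zq_lat = 0.8 * z_sleep + rng.normal(0, 0.6, T)
        sleep_quality = np.clip(np.round(4.5 + 1.2 * zq_lat), 1, 7).astype(int)

        # soreness driven by yesterday's and recent load; stress is AR noise
        tl_lag1 = np.concatenate([[tl.mean()], tl[:-1]])
        ewma = pd.Series(tl).ewm(span=7, adjust=False).mean().to_numpy()
        zs_lat = 0.55 * _zscore(tl_lag1) + 0.35 * _zscore(ewma) + 0.55 * rng.normal(0, 1, T)
        zs_lat = zs_lat / np.sqrt(0.55**2 + 0.35**2 + 0.55**2)
        soreness = np.clip(np.round(3.5 + 1.5 * zs_lat), 1, 10).astype(int)
        zt_lat = np.empty(T)
        zt_lat[0] = rng.normal()
        innov = rng.normal(0, np.sqrt(1 - 0.5**2), T)
        for t in range(1, T):
            zt_lat[t] = 0.5 * zt_lat[t - 1] + innov[t]
        life_stress = np.clip(np.round(3.0 + 1.1 * zt_lat), 1, 7).astype(int)

        cho_ma3 = pd.Series(cho).rolling(3, min_periods=1).mean().shift(1).fillna(cho.mean()).to_numpy()
        cov_parts.append(
            pd.DataFrame(
                {
                    "participant_id": profile.participant_id,
                    "date": dates,
                    "z_soreness": zs_lat,
                    "z_life_stress": zt_lat,
                    "z_sleep_quality": zq_lat,
                    "z_sleep_h": z_sleep,
                    "z_protein": (protein - profile.diet_means["protein_g_kg"]) / _WITHIN_SD["protein_g_kg"],
                    "z_cho_ma3": _zscore(cho_ma3),
                    "z_tl_lag1": _zscore(tl_lag1),
                    "tl_centered_lag1": tl_lag1 - tl_lag1.mean(),
                    "sleep_dev": sleep - profile.sleep_mean_h,
                }
            )
        )
        daily_parts.append(
            pd.DataFrame(
                {
                    "participant_id": profile.participant_id,
                    "date": dates,
                    "kcal": np.round(kcal_kg * mass, 0),
                    "cho_g_kg": np.round(cho, 2),
                    "fat_g_kg": np.round(fat, 2),
                    "protein_g_kg": np.round(protein, 2),
                    "sleep_h": np.round(sleep, 2),
                    "sleep_quality": sleep_quality,
                    "soreness": soreness,
                    "life_stress": life_stress,
                    "resting_hr": 0.0,  # filled after HRV simulation
                    "body_mass_kg": np.round(mass, 1),
                }
            )
        )

    daily = pd.concat(daily_parts, ignore_index=True)
    cov = pd.concat(cov_parts, ignore_index=True)
    am_prs, ln_rmssd = simulate_outcomes(
        profiles,
        cov,
        noise_sd_prs=config.noise_sd_prs,
        hrv_noise_sd=config.hrv_noise_sd,
        rngs=outcome_rngs,
    )
    daily["am_prs"] = np.round(am_prs, 1)
    daily["ln_rmssd"] = np.round(ln_rmssd, 4)
    for profile, rng2 in zip(profiles, outcome_rngs):
        mask = daily["participant_id"] == profile.participant_id
        dev = daily.loc[mask, "ln_rmssd"].to_numpy() - profile.hrv_baseline
        hr = profile.hr_baseline - 8.0 * dev + rng2.normal(0, 3.0, mask.sum())
        daily.loc[mask, "resting_hr"] = np.round(np.clip(hr, 30, 110), 0)

    sessions = pd.DataFrame(
        all_sessions,
        columns=["participant_id", "date", "modality", "duration_min", "rpe", "pre_ex_cho_g"],
    )
    daily["date"] = daily["date"].dt.date.astype(str)

    if config.missing_rate > 0:
        daily = apply_missingness(daily, config.missing_rate, miss_seed)

    truth = GroundTruth(
        profiles=profiles,
        effect_sizes=dict(config.effect_sizes),
        true_features=_true_feature_map(config),
        config=config.to_dict(),
    )
    return sessions, daily, truth


def _true_feature_map(config: GeneratorConfig) -> dict[str, list[str]]:
    """Generative drivers per outcome, ranked by global |effect|."""
    prs = [
        (abs(v), _PRS_DRIVER_COLUMNS[k])
        for k, v in config.effect_sizes.items()
        if k.startswith("prs_") and v != 0.0
    ]
    prs.sort(reverse=True)
    hrv = ["ln_rmssd__lag1"]
    if config.effect_sizes.get("hrv_load_lag1", 0.0) != 0.0:
        hrv.append("tl__lag1")
    if config.effect_sizes.get("hrv_sleep", 0.0) != 0.0:
        hrv.append("sleep_h")
    return {"am_prs": [name for _, name in prs], "hrv_change": hrv}


def apply_missingness(
    table: pd.DataFrame,
    missing_rate: float,
    seed: int,
    columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Blank an MCAR fraction of eligible predictor cells; reproducible."""
    if not 0.0 <= missing_rate < 0.2:
        raise ConfigurationError("missing_rate: must be in [0, 0.2)")
    out = table.copy()
    if missing_rate == 0.0:
        return out
    cols = [c for c in (columns or ELIGIBLE_MISSING_COLUMNS) if c in out.columns]
    rng = np.random.default_rng(seed)
    mask = rng.random((len(out), len(cols))) < missing_rate
    for j, c in enumerate(cols):
        col = out[c]
        if col.dtype.kind in "iu":
            out[c] = col.astype(float)
        out.loc[mask[:, j], c] = np.nan
    return out


def write_cohort(
    sessions: pd.DataFrame,
    daily: pd.DataFrame,
    truth: GroundTruth,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Persist the two log tables as CSV and the ground truth as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "sessions": out / "sessions.csv",
        "daily": out / "daily.csv",
        "ground_truth": out / "ground_truth.json",
    }
    sessions.to_csv(paths["sessions"], index=False)
    daily.to_csv(paths["daily"], index=False)
    truth.to_json(paths["ground_truth"])
    return paths
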