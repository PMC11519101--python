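"""Configuration objects for the synthetic cohort generator and the pipeline.

All stochastic components take a single integer ``seed``; child seeds are
derived deterministically with :class:`numpy.random.SeedSequence` so partial
re-runs of a pipeline stage reproduce bit-identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml


class ConfigurationError(ValueError):
    """Raised when a config field is out of its documented range."""


#: Global outcome-model coefficients of the simulator.
#:
#: ``prs_*`` coefficients are AM PRS points per SD of the (latent) driver,
#: except ``prs_lag1`` which is a day-to-day autoregressive coefficient on
#: the centered previous-morning score.  ``hrv_load_lag1`` is Ln rMSSD units
#: per unit of previous-day training load; ``hrv_sleep`` is Ln rMSSD units
#: per hour of sleep above the athlete's personal mean.  Drivers with a 0.0
#: default are inactive in the homogeneous cohort but become personal
#: predictors when ``heterogeneity_sd > 0``.
DEFAULT_EFFECT_SIZES: dict[str, float] = {
    "prs_soreness": -4.5,
    "prs_life_stress": -3.5,
    "prs_sleep_quality": 3.5,
    "prs_lag1": 0.35,
    "prs_sleep_h": 0.0,
    "prs_protein": 0.0,
    "prs_cho_ma3": 0.0,
    "prs_tl_lag1": 0.0,
    "hrv_load_lag1": -3.5e-4,
    "hrv_sleep": 0.03,
}

#: PRS drivers eligible for per-athlete coefficient deviations.
HETEROGENEITY_POOL: tuple[str, ...] = (
    "prs_soreness",
    "prs_life_stress",
    "prs_sleep_quality",
    "prs_sleep_h",
    "prs_protein",
    "prs_cho_ma3",
    "prs_tl_lag1",
)

#: Mon..Sun probability that an athlete trains on that weekday.  Weekday rest
#: probability ~0.15; weekends are near-certain training days, as is typical
#: for amateur endurance schedules built around long weekend sessions.
DEFAULT_TRAIN_PROB: tuple[float, ...] = (0.85, 0.85, 0.85, 0.85, 0.85, 0.97, 0.95)

#: Mon..Sun multiplier on expected session volume (weekend long sessions).
DEFAULT_VOLUME_MULT: tuple[float, ...] = (0.8, 0.9, 0.8, 0.9, 0.8, 1.6, 1.4)


@dataclass
class WeeklyPattern:
    """Per-weekday training probability and volume multipliers (Mon..Sun)."""

    train_prob: tuple[float, ...] = DEFAULT_TRAIN_PROB
    volume_mult: tuple[float, ...] = DEFAULT_VOLUME_MULT

    def validate(self) -> None:
        if len(self.train_prob) != 7 or len(self.volume_mult) != 7:
            raise ConfigurationError("weekly_pattern: needs 7 weekday entries")
        if not all(0.0 <= p <= 1.0 for p in self.train_prob):
            raise ConfigurationError("weekly_pattern.train_prob: outside [0, 1]")
        if not all(m > 0 for m in self.volume_mult):
            raise ConfigurationError("weekly_pattern.volume_mult: must be > 0")


@dataclass
class GeneratorConfig:
    """Study-scale defaults for the simulated endurance cohort.

    Defaults mirror a 12-week observational monitoring block of ~43
    endurance athletes: ~84 tracked days each, mean sleep 7.5 h, mean intake
    4.1/1.9/1.7 g/kg CHO/protein/fat at ~39.6 kcal/kg, ~11.8 training hours
    per week, and ~2.4% of predictor cells missing.
    """

    n_participants: int = 43
    n_days: int = 84
    missing_rate: float = 0.024
    weekly_pattern: WeeklyPattern = field(default_factory=WeeklyPattern)
    effect_sizes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_SIZES)
    )
    heterogeneity_sd: float = 0.0
    noise_sd_prs: float = 11.0
    hrv_phi_range: tuple[float, float] = (0.45, 0.75)
    hrv_noise_sd: float = 0.28
    seed: int = 0
    start_date: str = "2023-01-02"  # a Monday

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ConfigurationError("n_participants: must be >= 2")
        if self.n_days < 21:
            raise ConfigurationError("n_days: must be >= 21 (rolling warm-up)")
        if not 0.0 <= self.missing_rate < 0.2:
            raise ConfigurationError("missing_rate: must be in [0, 0.2)")
        lo, hi = self.hrv_phi_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigurationError("hrv_phi_range: must be within (0, 1)")
        if self.noise_sd_prs < 0:
            raise ConfigurationError("noise_sd_prs: must be >= 0")
        if self.hrv_noise_sd < 0:
            raise ConfigurationError("hrv_noise_sd: must be >= 0")
        if self.heterogeneity_sd < 0:
            raise ConfigurationError("heterogeneity_sd: must be >= 0")
        unknown = set(self.effect_sizes) - set(DEFAULT_EFFECT_SIZES)
        if unknown:
            raise ConfigurationError(f"effect_sizes: unknown keys {sorted(unknown)}")
        self.weekly_pattern.validate()

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "GeneratorConfig":
        d = dict(d)
        wp = d.pop("weekly_pattern", None)
        cfg = cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})
        extra = set(d) - set(cls.__dataclass_fields__)
        if extra:
            raise ConfigurationError(f"generator config: unknown keys {sorted(extra)}")
        if wp is not None:
            cfg.weekly_pattern = WeeklyPattern(
                train_prob=tuple(wp["train_prob"]),
                volume_mult=tuple(wp["volume_mult"]),
            )
        if "hrv_phi_range" in d:
            cfg.hrv_phi_range = tuple(d["hrv_phi_range"])  # type: ignore[assignment]
        eff = dict(DEFAULT_EFFECT_SIZES)
        eff.update(d.get("effect_sizes", {}))
        cfg.effect_sizes = eff
        cfg.validate()
        return cfg


_PIPELINE_KEYS = {
    "seed",
    "out_dir",
    "generator",
    "sessions_csv",
    "daily_csv",
    "n_lags",
    "correlation_threshold",
    "variable_sets",
    "outcomes",
    "group_learners",
    "individual_learners",
    "adjust_method",
    "same_day_policy",
    "min_weekly_hours",
    "min_logged_fraction",
    "min_days",
    "n_bootstrap",
    "cv_repeats",
    "cv_folds",
    "importance_repeats",
}


@dataclass
class PipelineConfig:
    """End-to-end run configuration; unknown keys are rejected."""

    seed: int = 0
    out_dir: str = "runs/run0"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    sessions_csv: str | None = None  # ingest instead of simulating
    daily_csv: str | None = None
    n_lags: int = 7
    correlation_threshold: float = 0.85
    variable_sets: tuple[str, ...] = ("MAIN", "ACTIONABLE")
    outcomes: tuple[str, ...] = ("am_prs", "hrv_change")
    group_learners: tuple[str, ...] = ("lasso",)
    individual_learners: tuple[str, ...] = ("lasso", "ridge", "knn")
    adjust_method: str = "sidak"
    same_day_policy: str = "morning_only"
    min_weekly_hours: float = 6.0
    min_logged_fraction: float = 0.85
    min_days: int = 42
    n_bootstrap: int = 500
    cv_repeats: int = 10
    cv_folds: int = 10
    importance_repeats: int = 10

    def validate(self) -> None:
        if self.n_lags < 0:
            raise ConfigurationError("n_lags: must be >= 0")
        if not 0 < self.correlation_threshold <= 1:
            raise ConfigurationError("correlation_threshold: must be in (0, 1]")
        if self.adjust_method not in ("sidak", "tukey"):
            raise ConfigurationError("adjust_method: must be 'sidak' or 'tukey'")
        if self.same_day_policy not in ("morning_only", "all_lag0"):
            raise ConfigurationError(
                "same_day_policy: must be 'morning_only' or 'all_lag0'"
            )
        for vs in self.variable_sets:
            if vs not in ("MAIN", "ACTIONABLE"):
                raise ConfigurationError(f"variable_sets: unknown set {vs!r}")
        for oc in self.outcomes:
            if oc not in ("am_prs", "hrv_change"):
                raise ConfigurationError(f"outcomes: unknown outcome {oc!r}")
        self.generator.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        unknown = set(raw) - _PIPELINE_KEYS
        if unknown:
            raise ConfigurationError(f"pipeline config: unknown keys {sorted(unknown)}")
        gen = GeneratorConfig.from_dict(raw.pop("generator", {}))
        cfg = cls(generator=gen)
        for k, v in raw.items():
            if k in ("variable_sets", "outcomes", "group_learners", "individual_learners"):
                v = tuple(v)
            setattr(cfg, k, v)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
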