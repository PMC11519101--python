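"""End-to-end orchestration: simulate/ingest -> features -> preprocess ->
fit -> interpret -> report, reproducible from (config, seed).

Each stage writes its artifact into the run directory and logs row/column
counts; a manifest of artifact SHA-256 hashes is written at the end so
reruns can be verified bit-identical.  The single pipeline seed is fanned
out to per-stage child seeds by stable derivation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .compare import compare_model_types, render_report
from .config import GeneratorConfig, PipelineConfig
from .features import build_feature_table
from .interpret import (
    aggregate_individual_importance,
    model_importance_scaled,
    partial_dependence,
    permutation_importance,
    top_k_features,
)
from .modeling import (
    bootstrap_metrics,
    fit_baseline,
    fit_group_model,
    fit_individual_models,
    fit_lmm_top5,
    make_learner,
)
from .preprocess import (
    apply_inclusion_rules,
    impute_features,
    impute_missing,
    markov_unfold,
    prune_correlated,
    select_variable_set,
)
from .synthetic import generate_cohort, write_cohort

logger = logging.getLogger("recoverml")

__all__ = ["ingest_logs", "run_pipeline", "stage_seeds"]

_SESSION_SCHEMA = ["participant_id", "date", "modality", "duration_min", "rpe", "pre_ex_cho_g"]
_DAILY_SCHEMA = [
    "participant_id", "date", "kcal", "cho_g_kg", "fat_g_kg", "protein_g_kg",
    "sleep_h", "sleep_quality", "soreness", "life_stress", "am_prs",
    "ln_rmssd", "resting_hr", "body_mass_kg",
]


class ValidationError(ValueError):
    """Raised when ingested logs violate the schema or value ranges."""


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic child seed per pipeline stage (all below 2**31)."""
    names = ["simulate", "fit", "individual", "interpret", "report"]
    children = np.random.SeedSequence([seed, 424243]).spawn(len(names))
    return {
        n: int(c.generate_state(1)[0] % (2**31 - 1)) for n, c in zip(names, children)
    }


def ingest_logs(sessions_csv: str | Path, daily_csv: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and range-check the two raw log tables.

    Violations are reported with row numbers (RPE outside 0-100, wellness
    scores outside their instruments' ranges, duplicate participant-days).
    """
    sessions = pd.read_csv(sessions_csv)
    daily = pd.read_csv(daily_csv)
    problems: list[str] = []
    for name, df, schema in (
        ("sessions", sessions, _SESSION_SCHEMA),
        ("daily", daily, _DAILY_SCHEMA),
    ):
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise ValidationError(f"{name} table missing columns: {missing}")

    def check(df, name, col, lo, hi, allow_na=True):
        v = df[col]
        bad = (~v.between(lo, hi)) & (v.notna() if allow_na else True)
        for i in df.index[bad]:
            problems.append(f"{name} row {i}: {col}={v[i]!r} outside [{lo}, {hi}]")

    check(sessions, "sessions", "rpe", 0, 100)
    check(sessions, "sessions", "duration_min", 1e-9, 24 * 60)
    check(sessions, "sessions", "pre_ex_cho_g", 0, 1000)
    check(daily, "daily", "sleep_quality", 1, 7)
    check(daily, "daily", "life_stress", 1, 7)
    check(daily, "daily", "soreness", 1, 10)
    check(daily, "daily", "am_prs", 0, 100)
    check(daily, "daily", "sleep_h", 0, 24)
    dup = daily.duplicated(["participant_id", "date"])
    for i in daily.index[dup]:
        problems.append(
            f"daily row {i}: duplicate participant-day "
            f"({daily.loc[i, 'participant_id']}, {daily.loc[i, 'date']})"
        )
    if problems:
        raise ValidationError("; ".join(problems))
    return sessions, daily


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    config.validate()
    seeds = stage_seeds(config.seed)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage: simulate or ingest -------------------------------------
    if config.sessions_csv and config.daily_csv:
        sessions, daily = ingest_logs(config.sessions_csv, config.daily_csv)
        logger.info("ingest: %d sessions, %d daily rows", len(sessions), len(daily))
    else:
        gen = GeneratorConfig.from_dict({**config.generator.to_dict(), "seed": seeds["simulate"]})
        sessions, daily, truth = generate_cohort(gen)
        write_cohort(sessions, daily, truth, out / "cohort")
        logger.info("simulate: %d sessions, %d daily rows", len(sessions), len(daily))

    # --- stage: preprocess + features ----------------------------------
    sessions, daily, report = apply_inclusion_rules(
        sessions, daily, config.min_weekly_hours, config.min_logged_fraction, config.min_days
    )
    report.table.to_csv(out / "inclusion_report.csv", index=False)
    daily = impute_missing(daily)
    features, manifest = build_feature_table(sessions, daily)
    features, outcome_missing = impute_features(features, manifest)
    features.to_csv(out / "features.csv", index=False)
    pd.DataFrame([vars(c) for c in manifest]).to_csv(out / "feature_manifest.csv", index=False)
    logger.info("features: %d rows x %d columns", *features.shape)

    group_fits, individual_fits = [], []
    comparisons, importance_tables, pd_tables = {}, {}, {}
    for outcome in config.outcomes:
        ds_full = markov_unfold(
            features, manifest, outcome, config.n_lags, config.same_day_policy, outcome_missing
        )
        ds_main = select_variable_set(ds_full, "MAIN")
        pruned, removed = prune_correlated(ds_main.X, config.correlation_threshold)
        ds_main.X = pruned
        logger.info(
            "%s: unfolded %d rows; MAIN %d columns after pruning %d",
            outcome, len(pruned), pruned.shape[1], len(removed),
        )

        # --- stage: group fits ------------------------------------------
        fits = {}
        for learner in config.group_learners:
            fits[learner] = fit_group_model(ds_main, learner, seeds["fit"], "MAIN")
        baseline = fit_baseline(ds_main)
        group_fits.extend([f.result for f in fits.values()] + [baseline.result])
        best_name = min(fits, key=lambda k: fits[k].result.rmse)
        best = fits[best_name]

        if "ACTIONABLE" in config.variable_sets:
            ds_act = select_variable_set(ds_full, "ACTIONABLE")
            pruned_act, _ = prune_correlated(ds_act.X, config.correlation_threshold)
            ds_act.X = pruned_act
            for learner in config.group_learners:
                group_fits.append(
                    fit_group_model(ds_act, learner, seeds["fit"], "ACTIONABLE").result
                )

        # --- stage: interpretation --------------------------------------
        imp = permutation_importance(
            best, n_repeats=config.importance_repeats, seed=seeds["interpret"]
        )
        importance_tables[f"group_{outcome}"] = imp.ranking()
        top5 = top_k_features(imp, 5)
        lmm = fit_lmm_top5(ds_main, top5)
        group_fits.append(lmm.result)
        pd_frames = []
        final_est = best.folds[0]["estimator"] if best.folds else None
        for feat in top5:
            if final_est is None or ds_main.X[feat].nunique() < 3:
                continue
            prof = partial_dependence(final_est, ds_main.X, feat)
            pd_frames.append(
                pd.DataFrame(
                    {"feature": feat, "grid": prof.grid, "mean_response": prof.mean_response}
                )
            )
        if pd_frames:
            pd_tables[outcome] = pd.concat(pd_frames, ignore_index=True)

        # --- stage: individual models -----------------------------------
        ind = fit_individual_models(
            ds_main,
            learners=config.individual_learners,
            seed=seeds["individual"],
            cv_folds=config.cv_folds,
            cv_repeats=config.cv_repeats,
            n_bootstrap=config.n_bootstrap,
        )
        individual_fits.extend(ind)
        reports = []
        for f in ind:
            mask = (ds_main.groups == f.participant_id).to_numpy()
            reports.append(
                model_importance_scaled(f, ds_main.X.loc[mask], ds_main.y.loc[mask])
            )
        if reports:
            importance_tables[f"individual_{outcome}"] = aggregate_individual_importance(reports)

        # per-participant linear top5 (group and individual) + baseline
        rmse_rows = []
        for f, rep in zip(ind, reports):
            pid = f.participant_id
            mask = (ds_main.groups == pid).to_numpy()
            Xp, yp = ds_main.X.loc[mask], ds_main.y.loc[mask].to_numpy(float)
            own5 = list(rep.ranking()["feature"].head(5))
            for label, feats in (("top5_individual", own5), ("top5_group", top5)):
                boot = bootstrap_metrics(
                    lambda: make_learner("ridge", seeds["individual"]),
                    Xp[feats], yp, B=min(config.n_bootstrap, 200), seed=seeds["individual"],
                )
                rmse_rows.append(
                    {"participant_id": pid, "model_type": label, "rmse": boot["rmse"].mean()}
                )
            boot0 = bootstrap_metrics(
                lambda: make_learner("intercept", 0), Xp.iloc[:, :1], yp,
                B=min(config.n_bootstrap, 200), seed=seeds["individual"],
            )
            rmse_rows.append(
                {"participant_id": pid, "model_type": "baseline", "rmse": boot0["rmse"].mean()}
            )
            rmse_rows.append({"participant_id": pid, "model_type": "best_MAIN", "rmse": f.rmse})
        if rmse_rows:
            comparisons[outcome] = compare_model_types(
                pd.DataFrame(rmse_rows), adjust_method=config.adjust_method
            )

    # --- stage: report ---------------------------------------------------
    paths = render_report(
        group_fits, individual_fits, comparisons, importance_tables, out, pd_tables
    )
    manifest_hashes = {
        str(p.relative_to(out)): _sha256(p) for p in sorted(out.rglob("*")) if p.is_file()
    }
    (out / "manifest.json").write_text(json.dumps(manifest_hashes, indent=2))
    return out
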