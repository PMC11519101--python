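"""Statistical comparison of model families and report rendering.

Per-participant RMSEs (one per model type) are compared with a
random-intercept linear mixed model — RMSE as the response, model type as a
fixed effect, participant as the random effect — followed by all pairwise
contrasts of the estimated marginal means.  Multiplicity is handled by the
Sidak adjustment (default), ``p_adj = 1 - (1 - p)^m``, or by the
Tukey studentized-range test; a compact letter display summarizes the
significance graph (types not sharing any letter differ at alpha = 0.05).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .modeling import FitResult, _fit_mixedlm

__all__ = [
    "ComparisonResult",
    "sidak_adjust",
    "compare_model_types",
    "letter_display",
    "render_report",
]

ALPHA = 0.05


@dataclass
class ComparisonResult:
    means: pd.DataFrame  # model_type, emmean, se, letters
    contrasts: pd.DataFrame  # pair, estimate, se, stat, p_raw, p_adj
    adjust_method: str
    missing_cells: pd.DataFrame | None = None


def sidak_adjust(p: float | np.ndarray, m: int) -> float | np.ndarray:
    """Sidak multiplicity adjustment: 1 - (1 - p)^m, capped at 1."""
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    out = np.minimum(1.0, 1.0 - (1.0 - p_arr) ** m)
    return float(out) if out.ndim == 0 else out


def compare_model_types(
    rmse_table: pd.DataFrame,
    adjust_method: str = "sidak",
    alpha: float = ALPHA,
) -> ComparisonResult:
    """Mixed-model comparison of per-participant RMSEs across model types.

    ``rmse_table`` is long-format with columns ``participant_id``,
    ``model_type``, ``rmse`` (one row per participant x type).  Missing
    cells are tolerated (reported, fit proceeds on available rows).
    """
    need = {"participant_id", "model_type", "rmse"}
    if not need <= set(rmse_table.columns):
        raise ValueError(f"rmse_table needs columns {sorted(need)}")
    types = sorted(rmse_table["model_type"].unique())
    if len(types) < 2:
        raise ValueError("need at least 2 model types")
    pids = sorted(rmse_table["participant_id"].unique())
    if len(pids) < 3:
        raise ValueError("need at least 3 participants")
    full = pd.MultiIndex.from_product([pids, types], names=["participant_id", "model_type"])
    present = rmse_table.set_index(["participant_id", "model_type"]).index
    missing = full.difference(present)
    missing_df = missing.to_frame(index=False) if len(missing) else None

    # intercept + treatment coding; marginal means recovered by contrasts
    dummies = pd.get_dummies(rmse_table["model_type"], drop_first=False)[types]
    exog = np.column_stack([np.ones(len(rmse_table)), dummies.to_numpy(float)[:, 1:]])
    y = rmse_table["rmse"].to_numpy(float)
    groups = rmse_table["participant_id"].to_numpy()
    fit = _fit_mixedlm(y, exog, groups)
    k = len(types)
    fe = np.asarray(fit.fe_params, dtype=float)[:k]
    cov_fe = np.asarray(fit.cov_params())[:k, :k]
    L = np.zeros((k, k))
    L[:, 0] = 1.0
    for t in range(1, k):
        L[t, t] = 1.0
    means = L @ fe
    cov = L @ cov_fe @ L.T
    df_resid = max(len(y) - len(types) - len(pids) + 1, 2)

    pairs = list(itertools.combinations(range(len(types)), 2))
    m = len(pairs)
    rows = []
    for i, j in pairs:
        est = means[i] - means[j]
        se = float(np.sqrt(max(cov[i, i] + cov[j, j] - 2 * cov[i, j], 0.0)))
        if se > 0:
            tstat = est / se
        else:  # degenerate fit: identical columns give estimate 0, p 1
            tstat = 0.0 if abs(est) < 1e-12 else np.inf * np.sign(est)
        p_raw = float(2 * stats.t.sf(abs(tstat), df_resid))
        if adjust_method == "sidak":
            p_adj = sidak_adjust(p_raw, m)
        elif adjust_method == "tukey":
            q = abs(tstat) * np.sqrt(2.0)
            p_adj = float(stats.studentized_range.sf(q, len(types), df_resid))
        else:
            raise ValueError(f"unknown adjustment {adjust_method!r}")
        rows.append(
            {
                "pair": f"{types[i]} - {types[j]}",
                "type_a": types[i],
                "type_b": types[j],
                "estimate": float(est),
                "se": se,
                "stat": float(tstat),
                "p_raw": p_raw,
                "p_adj": min(1.0, p_adj),
            }
        )
    contrasts = pd.DataFrame(rows)
    letters = letter_display(types, contrasts, alpha=alpha)
    means_df = pd.DataFrame(
        {
            "model_type": types,
            "emmean": means,
            "se": np.sqrt(np.diag(cov)),
            "letters": [letters[t] for t in types],
        }
    ).sort_values("emmean").reset_index(drop=True)
    return ComparisonResult(
        means=means_df, contrasts=contrasts, adjust_method=adjust_method,
        missing_cells=missing_df,
    )


def letter_display(
    types: list[str], contrasts: pd.DataFrame, alpha: float = ALPHA
) -> dict[str, str]:
    """Compact letter display via the insert-and-absorb algorithm.

    Guarantees that two types share a letter iff they are not significantly
    different (adjusted p > alpha) under the supplied pairwise contrasts.
    """
    columns: list[set[str]] = [set(types)]
    sig_pairs = [
        (r["type_a"], r["type_b"])
        for _, r in contrasts.iterrows()
        if r["p_adj"] <= alpha
    ]
    for a, b in sig_pairs:
        new_cols = []
        for col in columns:
            if a in col and b in col:
                new_cols.append(col - {a})
                new_cols.append(col - {b})
            else:
                new_cols.append(col)
        # absorb: drop columns that are subsets of another
        columns = [
            c
            for i, c in enumerate(new_cols)
            if c and not any(i != j and c < other for j, other in enumerate(new_cols))
        ]
        # dedupe
        uniq = []
        for c in columns:
            if c not in uniq:
                uniq.append(c)
        columns = uniq
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    # letter order follows ascending mean-agnostic column order; stable
    out = {t: "" for t in types}
    for letter, col in zip(alphabet, columns):
        for t in types:
            if t in col:
                out[t] += letter
    return out


def render_report(
    group_fits: list[FitResult],
    individual_fits: list[FitResult],
    comparisons: dict[str, ComparisonResult],
    importance_tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    pd_tables: dict[str, pd.DataFrame] | None = None,
) -> dict[str, Path]:
    """Write the report bundle: comparison tables, per-participant RMSE long
    table, importance/PD artifacts, and a markdown summary.

    Requires at least one baseline fit per outcome present among
    ``group_fits`` — comparisons are meaningless without the intercept-only
    reference.
    """
    out = Path(out_dir)
    (out / "tables").mkdir(parents=True, exist_ok=True)
    (out / "figures").mkdir(parents=True, exist_ok=True)
    outcomes = {f.outcome for f in group_fits}
    for oc in outcomes:
        if not any(f.learner == "intercept" and f.outcome == oc for f in group_fits):
            raise ValueError(f"missing intercept-only baseline for outcome {oc!r}")

    paths: dict[str, Path] = {}
    group_df = pd.DataFrame([f.to_row() for f in group_fits])
    group_df = group_df.sort_values(["outcome", "rmse"]).reset_index(drop=True)
    paths["group_models"] = out / "tables" / "group_models.csv"
    group_df.to_csv(paths["group_models"], index=False)

    if individual_fits:
        ind_rows = []
        for f in individual_fits:
            row = f.to_row()
            row["rmse_sd"] = f.rmse_sd
            row["r_squared_sd"] = f.r_squared_sd
            ind_rows.append(row)
        ind_df = pd.DataFrame(ind_rows).sort_values(
            ["outcome", "variables", "participant_id"]
        )
        paths["individual_models"] = out / "tables" / "individual_models.csv"
        ind_df.to_csv(paths["individual_models"], index=False)
        # Fig-1-style long table of per-participant RMSEs
        paths["rmse_long"] = out / "figures" / "rmse_by_participant.csv"
        ind_df[["outcome", "variables", "participant_id", "rmse"]].to_csv(
            paths["rmse_long"], index=False
        )

    comp_frames = []
    for oc, comp in comparisons.items():
        means = comp.means.assign(outcome=oc, adjust=comp.adjust_method)
        comp_frames.append(means)
        comp.contrasts.assign(outcome=oc).to_csv(
            out / "tables" / f"contrasts_{oc}.csv", index=False
        )
    if comp_frames:
        paths["comparison"] = out / "tables" / "comparison.csv"
        pd.concat(comp_frames, ignore_index=True).to_csv(paths["comparison"], index=False)

    for name, tbl in importance_tables.items():
        p = out / "figures" / f"importance_{name}.csv"
        tbl.to_csv(p, index=False)
        paths[f"importance_{name}"] = p
    for name, tbl in (pd_tables or {}).items():
        p = out / "figures" / f"partial_dependence_{name}.csv"
        tbl.to_csv(p, index=False)
        paths[f"pd_{name}"] = p

    lines = ["# Recovery model report", ""]
    for oc in sorted(outcomes):
        lines.append(f"## Outcome: {oc}")
        sub = group_df[group_df["outcome"] == oc]
        lines.append("")
        lines.append(sub.to_string(index=False))
        lines.append("")
        if oc in comparisons:
            lines.append("Model-type comparison (estimated marginal means):")
            lines.append(comparisons[oc].means.to_string(index=False))
            lines.append("")
    paths["report"] = out / "report.md"
    paths["report"].write_text("\n".join(lines))
    return paths
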