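"""Variable-importance rankings and partial-dependence profiles.

Permutation importance measures the increase in prediction error after
randomly permuting one feature; for LOSO-validated group models it is
computed on the held-out predictions (each fold's model is scored on its
own test participant with the feature shuffled within that block), so the
scores reflect out-of-sample structure rather than training fit.  Model-
based importance for individual models uses |standardized coefficient| for
linear learners (falling back to permutation otherwise) scaled to sum to 1,
which makes rankings comparable across participants whose best models
differ.  Lagged copies of a variable are reported as distinct features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .modeling import FitResult, GroupModelFit, score_predictions

__all__ = [
    "ImportanceReport",
    "PDProfile",
    "permutation_importance",
    "model_importance_scaled",
    "aggregate_individual_importance",
    "partial_dependence",
    "top_k_features",
]


@dataclass
class ImportanceReport:
    table: pd.DataFrame  # feature, importance (mean), sd
    method: str  # permutation | model_based_scaled
    model: str = ""
    repeats: pd.DataFrame | None = None  # feature x repeat distribution

    def ranking(self) -> pd.DataFrame:
        return self.table.sort_values(
            ["importance", "feature"], ascending=[False, True]
        ).reset_index(drop=True)


@dataclass
class PDProfile:
    feature: str
    grid: np.ndarray
    mean_response: np.ndarray
    individual: np.ndarray | None = None  # rows x grid

    def slope(self) -> float:
        return float(np.polyfit(self.grid, self.mean_response, 1)[0])


def permutation_importance(
    fit: GroupModelFit,
    n_repeats: int = 10,
    seed: int = 0,
    features: list[str] | None = None,
) -> ImportanceReport:
    """Held-out permutation importance of a LOSO-validated group model.

    importance(f) = pooled held-out RMSE with feature f permuted minus the
    intact pooled RMSE, averaged over ``n_repeats`` shuffles.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    ds = fit.dataset
    feats = features or list(ds.X.columns)
    missing = [f for f in feats if f not in ds.X.columns]
    if missing:
        raise KeyError(f"features absent from design matrix: {missing}")
    rng = np.random.default_rng(seed)
    col_idx = {c: i for i, c in enumerate(ds.X.columns)}
    Xmat = ds.X.to_numpy(float)
    y = ds.y.to_numpy(float)

    # intact pooled held-out error
    n_total = sum(len(f["test_idx"]) for f in fit.folds)
    base_sse = 0.0
    fold_blocks = []
    for f in fit.folds:
        idx = f["test_idx"]
        Xb = Xmat[idx]
        pred = np.asarray(f["estimator"].predict(Xb))
        base_sse += float(np.sum((y[idx] - pred) ** 2))
        fold_blocks.append((f["estimator"], idx, Xb))
    base_rmse = np.sqrt(base_sse / n_total)

    means, sds = [], []
    rep_matrix = np.empty((len(feats), n_repeats))
    for fi, feat in enumerate(feats):
        j = col_idx[feat]
        sse = np.zeros(n_repeats)
        for est, idx, Xb in fold_blocks:
            nb = len(idx)
            # all repeats stacked into one prediction call per fold
            Xp = np.tile(Xb, (n_repeats, 1))
            for r in range(n_repeats):
                Xp[r * nb : (r + 1) * nb, j] = Xb[rng.permutation(nb), j]
            pred = np.asarray(est.predict(Xp)).reshape(n_repeats, nb)
            sse += np.sum((y[idx][None, :] - pred) ** 2, axis=1)
        rep_matrix[fi] = np.sqrt(sse / n_total) - base_rmse
        means.append(rep_matrix[fi].mean())
        sds.append(rep_matrix[fi].std(ddof=1) if n_repeats > 1 else 0.0)
    table = pd.DataFrame({"feature": feats, "importance": means, "sd": sds})
    reps = pd.DataFrame(rep_matrix, index=feats)
    return ImportanceReport(table=table, method="permutation",
                            model=fit.result.learner, repeats=reps)


def _linear_coefficients(estimator) -> np.ndarray | None:
    """Standardized coefficients of a (possibly CV-wrapped) linear pipeline."""
    est = estimator
    if hasattr(est, "best_estimator_"):
        est = est.best_estimator_
    if hasattr(est, "named_steps"):
        model = est.named_steps.get("model")
        if model is not None and hasattr(model, "coef_"):
            return np.asarray(model.coef_, dtype=float)
    if hasattr(est, "coef_"):
        return np.asarray(est.coef_, dtype=float)
    return None


def model_importance_scaled(
    fit_result: FitResult,
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    n_repeats: int = 5,
    seed: int = 0,
) -> ImportanceReport:
    """Model-based importance of one individual model, scaled to sum to 1.

    Linear learners use |standardized coefficient|; learners without
    coefficients fall back to (resubstitution) permutation importance.  An
    all-zero importance vector degrades to uniform with a warning.
    """
    est = fit_result.hyperparameters.get("fitted")
    if est is None:
        raise ValueError("fit_result does not carry a fitted estimator")
    coefs = _linear_coefficients(est)
    feats = list(X.columns)
    if coefs is not None and len(coefs) == len(feats):
        raw = np.abs(coefs)
    else:
        rng = np.random.default_rng(seed)
        Xmat = np.asarray(X, dtype=float)
        yv = np.asarray(y, dtype=float)
        base = np.sqrt(np.mean((yv - est.predict(Xmat)) ** 2))
        raw = np.zeros(len(feats))
        for j in range(len(feats)):
            incr = 0.0
            for _ in range(n_repeats):
                Xp = Xmat.copy()
                Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
                incr += np.sqrt(np.mean((yv - est.predict(Xp)) ** 2)) - base
            raw[j] = max(incr / n_repeats, 0.0)
    total = raw.sum()
    if total == 0:
        warnings.warn("all importances zero; returning uniform vector")
        raw = np.ones(len(feats))
        total = raw.sum()
    table = pd.DataFrame(
        {"feature": feats, "importance": raw / total, "sd": 0.0}
    )
    return ImportanceReport(table=table, method="model_based_scaled",
                            model=fit_result.learner)


def aggregate_individual_importance(reports: list[ImportanceReport]) -> pd.DataFrame:
    """Mean scaled importance per feature across participants' models.

    Features absent from a participant's model count as 0 for that
    participant, so the aggregate stays a proper average over athletes.
    """
    if not reports:
        raise ValueError("no importance reports supplied")
    all_feats = sorted({f for r in reports for f in r.table["feature"]})
    acc = pd.DataFrame(0.0, index=all_feats, columns=range(len(reports)))
    for i, r in enumerate(reports):
        s = r.table.set_index("feature")["importance"]
        acc.loc[s.index, i] = s
    out = pd.DataFrame(
        {"feature": all_feats, "importance": acc.mean(axis=1).to_numpy()}
    )
    return out.sort_values(
        ["importance", "feature"], ascending=[False, True]
    ).reset_index(drop=True)


def partial_dependence(
    model,
    X: pd.DataFrame,
    feature: str,
    grid_size: int = 20,
    keep_individual: bool = False,
) -> PDProfile:
    """Partial-dependence profile of one continuous feature.

    The grid spans the 5th-95th percentile of the observed feature; at each
    grid value the feature column is set to that value for every row and
    predictions are averaged (per-row profiles optionally retained).
    """
    if feature not in X.columns:
        raise KeyError(f"feature {feature!r} not in design matrix")
    col = X[feature].to_numpy(float)
    lo, hi = np.percentile(col, [5, 95])
    if lo == hi:
        raise ValueError(f"feature {feature!r} has zero variance over the grid span")
    grid = np.linspace(lo, hi, grid_size)
    j = list(X.columns).index(feature)
    Xmat = X.to_numpy(float)
    profiles = np.empty((len(X), grid_size)) if keep_individual else None
    means = np.empty(grid_size)
    for gi, val in enumerate(grid):
        Xg = Xmat.copy()
        Xg[:, j] = val
        pred = np.asarray(model.predict(Xg))
        means[gi] = pred.mean()
        if keep_individual:
            profiles[:, gi] = pred
    return PDProfile(feature=feature, grid=grid, mean_response=means, individual=profiles)


def top_k_features(report: ImportanceReport, k: int = 5) -> list[str]:
    """Top-k features by mean importance; ties broken alphabetically."""
    if k > len(report.table):
        raise ValueError("k exceeds number of features")
    ranked = report.ranking()
    return list(ranked["feature"].head(k))
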